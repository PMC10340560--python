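"""Filtering, resampling, and segmentation of recordings into labeled epochs.

The preprocessing chain is: zero-phase Butterworth low-pass (default 64 Hz)
plus a zero-phase 50 Hz notch for power-line noise, polyphase resampling to
the analysis rate (default 128 Hz, whose Nyquist of 64 Hz makes the
nine-level dyadic subband edges land exactly on the named band boundaries),
then segmentation into consecutive non-overlapping epochs of 4096 samples.

An epoch is labeled ictal when the fraction of its samples covered by
ictal annotations reaches the overlap threshold (default 0.5); otherwise
it is interictal. Labeling depends only on the annotations, never on the
signal content.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from fractions import Fraction
import logging
import math

import numpy as np
import scipy.signal as sig

from .errors import ConfigurationError, ValidationError
from .io import Interval, Recording

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Filtering / epoching parameters.

    Attributes
    ----------
    lowpass_cutoff_hz
        Butterworth low-pass cutoff (-3 dB), Hz.
    lowpass_order
        Butterworth order for a single pass; the filter is applied
        forward-backward, doubling the effective magnitude roll-off.
    notch_hz, notch_bandwidth_hz
        Power-line notch center and -3 dB bandwidth.
    analysis_fs_hz
        Target rate after resampling. 128 Hz aligns the dyadic wavelet
        bands with the nominal band table (D1 = 32-64 Hz, A9 = 0-0.125 Hz).
    epoch_len_samples
        Epoch length at the analysis rate; must be a power of two >= 512
        so a nine-level decomposition is feasible.
    epoch_label_overlap_threshold
        Minimum ictal-coverage fraction for an epoch to be labeled ictal.
    """

    lowpass_cutoff_hz: float = 64.0
    lowpass_order: int = 6
    notch_hz: float = 50.0
    notch_bandwidth_hz: float = 2.0
    analysis_fs_hz: float = 128.0
    epoch_len_samples: int = 4096
    epoch_label_overlap_threshold: float = 0.5

    def __post_init__(self) -> None:
        n = self.epoch_len_samples
        if n < 512 or (n & (n - 1)) != 0:
            raise ConfigurationError(
                f"epoch_len_samples must be a power of two >= 512, got {n}"
            )
        if not 0.0 <= self.epoch_label_overlap_threshold <= 1.0:
            raise ConfigurationError("overlap threshold must lie in [0, 1]")
        if self.lowpass_cutoff_hz > self.analysis_fs_hz / 2:
            raise ConfigurationError(
                "lowpass cutoff must not exceed the analysis Nyquist rate"
            )

    def validate_against(self, fs: float) -> None:
        if fs < 2 * self.lowpass_cutoff_hz:
            raise ConfigurationError(
                f"sampling rate {fs} Hz too low for a {self.lowpass_cutoff_hz} Hz cutoff"
            )
        if self.analysis_fs_hz > fs:
            raise ConfigurationError("upsampling to the analysis rate is not supported")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EpochSet:
    """Fixed-length labeled epochs cut from one or more recordings.

    ``epochs`` has shape (n_epochs, n_channels, epoch_len); ``origin``
    records, per epoch, the source recording id and the epoch's start
    sample in analysis-rate coordinates.
    """

    fs: float
    epoch_len: int
    channel_names: tuple[str, ...]
    epochs: np.ndarray
    labels: np.ndarray  # dtype object/str, values in {"ictal", "interictal"}
    origin: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.epochs.ndim != 3:
            raise ValidationError("epochs must be (n_epochs, n_channels, epoch_len)")
        if self.epochs.shape[2] != self.epoch_len:
            raise ValidationError("epoch tensor length disagrees with epoch_len")
        if len(self.labels) != self.n_epochs or len(self.origin) != self.n_epochs:
            raise ValidationError("labels/origin must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def subset(self, idx: np.ndarray) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            fs=self.fs,
            epoch_len=self.epoch_len,
            channel_names=self.channel_names,
            epochs=self.epochs[idx],
            labels=self.labels[idx],
            origin=[self.origin[i] for i in idx],
        )


def concat_epochsets(sets: list[EpochSet]) -> EpochSet:
    """Concatenate epoch sets that share rate, length, and channel order."""
    if not sets:
        raise ValidationError("no epoch sets to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if (
            s.fs != first.fs
            or s.epoch_len != first.epoch_len
            or s.channel_names != first.channel_names
        ):
            raise ValidationError("epoch sets are not compatible for concatenation")
    return EpochSet(
        fs=first.fs,
        epoch_len=first.epoch_len,
        channel_names=first.channel_names,
        epochs=np.concatenate([s.epochs for s in sets], axis=0),
        labels=np.concatenate([s.labels for s in sets]),
        origin=[o for s in sets for o in s.origin],
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def design_lowpass(cfg: PreprocessConfig, fs: float) -> np.ndarray:
    """Second-order sections of the Butterworth low-pass at rate ``fs``."""
    return sig.butter(cfg.lowpass_order, cfg.lowpass_cutoff_hz, fs=fs, output="sos")

def design_notch(cfg: PreprocessConfig, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """(b, a) of the second-order IIR notch at rate ``fs``."""
    q = cfg.notch_hz / cfg.notch_bandwidth_hz
    return sig.iirnotch(cfg.notch_hz, q, fs=fs)


def apply_filters(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Apply the low-pass and notch, zero-phase, identically to every channel."""
    cfg.validate_against(rec.fs)
    sos = design_lowpass(cfg, rec.fs)
    filtered = sig.sosfiltfilt(sos, rec.data, axis=1)
    if cfg.notch_hz < rec.fs / 2:
        b, a = design_notch(cfg, rec.fs)
        filtered = sig.filtfilt(b, a, filtered, axis=1)
    return rec.replace(data=filtered)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_analysis_rate(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Polyphase-resample to ``cfg.analysis_fs_hz``; rescales annotations.

    A no-op (same object content) when the recording is already at the
    analysis rate. Annotation starts are floored and ends ceiled in the
    new coordinates, preserving half-open semantics.
    """
    cfg.validate_against(rec.fs)
    if rec.fs == cfg.analysis_fs_hz:
        return rec
    ratio = Fraction(cfg.analysis_fs_hz / rec.fs).limit_denominator(10_000)
    data = sig.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    r = float(ratio)
    n_new = data.shape[1]
    annotations = [
        Interval(
            math.floor(iv.start * r),
            min(n_new, math.ceil(iv.end * r)),
            iv.label,
        )
        for iv in rec.annotations
    ]
    return rec.replace(data=data, fs=cfg.analysis_fs_hz, annotations=annotations)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _ictal_coverage(annotations: list[Interval], start: int, end: int) -> int:
    covered = 0
    for iv in annotations:
        if iv.label == "ictal":
            covered += max(0, min(end, iv.end) - max(start, iv.start))
    return covered


def segment_epochs(
    rec: Recording, cfg: PreprocessConfig, unlabeled: str = "interictal"
) -> EpochSet:
    """Cut a recording into consecutive non-overlapping labeled epochs.

    The trailing partial window is discarded. ``unlabeled`` controls epochs
    touched by no annotation at all: ``"interictal"`` (default: background
    is between-seizure activity) or ``"exclude"``.
    """
    if unlabeled not in ("interictal", "exclude"):
        raise ConfigurationError(f"unknown unlabeled policy {unlabeled!r}")
    if rec.fs != cfg.analysis_fs_hz:
        raise ConfigurationError(
            f"segment_epochs expects the analysis rate {cfg.analysis_fs_hz} Hz, "
            f"recording is at {rec.fs} Hz"
        )
    L = cfg.epoch_len_samples
    n_epochs = rec.n_samples // L
    if n_epochs == 0:
        logger.warning(
            "recording %s shorter than one epoch (%d < %d samples)",
            rec.recording_id, rec.n_samples, L,
        )
    windows, labels, origin = [], [], []
    for k in range(n_epochs):
        start, end = k * L, (k + 1) * L
        ictal_frac = _ictal_coverage(rec.annotations, start, end) / L
        if ictal_frac >= cfg.epoch_label_overlap_threshold:
            label = "ictal"
        else:
            any_overlap = any(
                min(end, iv.end) > max(start, iv.start) for iv in rec.annotations
            )
            if not any_overlap and unlabeled == "exclude":
                continue
            label = "interictal"
        windows.append(rec.data[:, start:end])
        labels.append(label)
        origin.append((rec.recording_id, start))
    epochs = (
        np.stack(windows)
        if windows
        else np.empty((0, rec.n_channels, L), dtype=np.float64)
    )
    return EpochSet(
        fs=rec.fs,
        epoch_len=L,
        channel_names=rec.channel_names,
        epochs=epochs,
        labels=np.array(labels, dtype=object),
        origin=origin,
    )


def preprocess_recording(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Filter then resample: the standard preprocessing chain."""
    return resample_to_analysis_rate(apply_filters(rec, cfg), cfg)
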