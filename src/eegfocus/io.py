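"""Reading and writing EEG recordings, annotations, and montage selection.

Two on-disk representations are supported:

* **EDF** (16-bit European Data Format), read through :mod:`mne`; a
  minimal EDF writer is provided so that synthetic recordings can be
  exported for tools that only speak EDF.
* A **plain matrix format**: a CSV with one column per channel (header row
  = channel names, one row per sample, values in microvolts), a key-value
  YAML sidecar ``<base>.meta.yaml`` holding sampling rate and identifiers,
  and an optional ``<base>.annotations.csv`` with columns
  ``start_s,end_s,label``. The matrix format round-trips float64 samples
  exactly and is the native format of the synthetic generator.

All sample intervals are half-open ``[start, end)`` and 0-based.
"""

from __future__ import annotations

import logging
import math
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import MontageError, ValidationError
from .montage import DEFAULT_MONTAGE, MontageSpec, normalize_channel_name

logger = logging.getLogger(__name__)

LABELS = ("ictal", "interictal")
SIDES = ("left", "right")


@dataclass(frozen=True)
class Interval:
    """A labeled half-open sample interval ``[start, end)``."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"unknown interval label {self.label!r}")
        if self.end <= self.start or self.start < 0:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class Recording:
    """A multichannel bipolar EEG recording.

    Attributes
    ----------
    fs
        Sampling rate in Hz.
    channel_names
        Ordered derivation names, one per data row.
    data
        Array of shape (n_channels, n_samples), microvolts.
    annotations
        Labeled sample intervals (expert or synthetic ground truth).
    true_laterality
        Optional ground-truth focus side, ``"left"``/``"right"``/None.
    """

    subject_id: str
    recording_id: str
    fs: float
    channel_names: tuple[str, ...]
    data: np.ndarray
    annotations: list[Interval] = field(default_factory=list)
    true_laterality: str | None = None

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.data = np.asarray(self.data, dtype=np.float64)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValidationError("data must be a (channels, samples) matrix")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if self.true_laterality is not None and self.true_laterality not in SIDES:
            raise ValidationError(f"unknown laterality {self.true_laterality!r}")
        n = self.n_samples
        by_label: dict[str, list[Interval]] = {}
        for iv in self.annotations:
            if iv.end > n:
                raise ValidationError(
                    f"annotation [{iv.start}, {iv.end}) exceeds recording length {n}"
                )
            by_label.setdefault(iv.label, []).append(iv)
        for label, ivs in by_label.items():
            ivs = sorted(ivs, key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"overlapping {label} annotations "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def replace(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, fs: float) -> list[Interval]:
    """Read labeled intervals from a CSV with columns start_s, end_s, label.

    Times in seconds are converted to sample indices at rate ``fs``
    (floor for starts, ceil for ends, half-open).
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if table.empty:
        return []
    required = {"start_s", "end_s", "label"}
    if not required.issubset(table.columns):
        raise ValidationError(
            f"annotation file {path} must have columns {sorted(required)}"
        )
    intervals = []
    for row in table.itertuples(index=False):
        start_s, end_s, label = float(row.start_s), float(row.end_s), str(row.label)
        if end_s <= start_s:
            raise ValidationError(
                f"annotation end {end_s} s must exceed start {start_s} s"
            )
        intervals.append(
            Interval(math.floor(start_s * fs), math.ceil(end_s * fs), label)
        )
    return intervals


def write_annotations(intervals: list[Interval], path: str | Path, fs: float) -> None:
    rows = [
        {"start_s": iv.start / fs, "end_s": iv.end / fs, "label": iv.label}
        for iv in intervals
    ]
    pd.DataFrame(rows, columns=["start_s", "end_s", "label"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Matrix format
# ---------------------------------------------------------------------------

def _matrix_paths(path: Path) -> tuple[Path, Path, Path]:
    base = path.with_suffix("") if path.suffix == ".csv" else path
    return base.with_suffix(".csv"), Path(str(base) + ".meta.yaml"), Path(
        str(base) + ".annotations.csv"
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording in the plain matrix format; returns the CSV path."""
    csv_path, meta_path, ann_path = _matrix_paths(Path(path))
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(rec.data.T, columns=list(rec.channel_names))
    # %.17g round-trips float64 exactly
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "subject_id": rec.subject_id,
        "recording_id": rec.recording_id,
        "fs": float(rec.fs),
        "true_laterality": rec.true_laterality,
    }
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    if rec.annotations:
        write_annotations(rec.annotations, ann_path, rec.fs)
    elif ann_path.exists():
        ann_path.unlink()
    return csv_path


def _read_matrix(path: Path) -> Recording:
    csv_path, meta_path, ann_path = _matrix_paths(path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    if not meta_path.exists():
        raise ValidationError(f"missing metadata sidecar {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    fs = float(meta["fs"])
    annotations = read_annotations(ann_path, fs) if ann_path.exists() else []
    return Recording(
        subject_id=str(meta.get("subject_id", "unknown")),
        recording_id=str(meta.get("recording_id", csv_path.stem)),
        fs=fs,
        channel_names=tuple(frame.columns),
        data=frame.to_numpy(dtype=np.float64).T,
        annotations=annotations,
        true_laterality=meta.get("true_laterality"),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne loads volts
    return Recording(
        subject_id=path.stem,
        recording_id=path.stem,
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        data=data_uv,
        annotations=[],
    )


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a 16-bit EDF file (one data record per second).

    The recording length must be a whole number of seconds at ``rec.fs``;
    amplitude resolution is limited by the 16-bit quantization of EDF.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF export requires an integer sampling rate")
    spr = int(round(fs))
    if rec.n_samples % spr != 0:
        raise ValidationError(
            "EDF export requires a whole number of one-second records"
        )
    n_records = rec.n_samples // spr
    ns = rec.n_channels

    phys_max = max(1.0, float(np.abs(rec.data).max()) * 1.0001)
    # store and reuse the 8-char header rendering so writer and reader
    # agree on the calibration exactly
    phys_max = float(f"{phys_max:.5g}") or 1.0
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((rec.data - phys_min) * scale + dig_min).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        raw = text.encode("ascii")[:width]
        return raw + b" " * (width - len(raw))

    header = b"".join(
        [
            pad("0", 8),
            pad(rec.subject_id, 80),
            pad(rec.recording_id, 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (ns + 1)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    fields = [
        (16, [pad(c, 16) for c in rec.channel_names]),
        (80, [pad("", 80)] * ns),
        (8, [pad("uV", 8)] * ns),
        (8, [pad(f"{phys_min:.5g}", 8)] * ns),
        (8, [pad(f"{phys_max:.5g}", 8)] * ns),
        (8, [pad(str(dig_min), 8)] * ns),
        (8, [pad(str(dig_max), 8)] * ns),
        (80, [pad("", 80)] * ns),
        (8, [pad(str(spr), 8)] * ns),
        (32, [pad("", 32)] * ns),
    ]
    signal_header = b"".join(b"".join(chunk) for _, chunk in fields)

    with open(path, "wb") as fh:
        fh.write(header + signal_header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(struct.pack(f"<{ns * spr}h", *block.ravel().tolist()))
    return path


# ---------------------------------------------------------------------------
# Montage-aware reading
# ---------------------------------------------------------------------------

def conform_to_montage(
    rec: Recording,
    montage: MontageSpec = DEFAULT_MONTAGE,
    require: str = "analysis",
) -> Recording:
    """Re-order channels to montage order, dropping unknown extras.

    ``require`` selects the channel set that must be present: ``"analysis"``
    (the 16 lateral channels) or ``"full"`` (all 18). Missing required
    channels raise :class:`MontageError` naming them.
    """
    resolved: dict[str, int] = {}
    for idx, name in enumerate(rec.channel_names):
        canonical = montage.resolve(name)
        if canonical is None:
            logger.warning(
                "dropping channel %r: not in montage (%s)", name, rec.recording_id
            )
        else:
            resolved[canonical] = idx
    required = (
        montage.full_channels if require == "full" else montage.analysis_channels
    )
    missing = [c for c in required if c not in resolved]
    if missing:
        raise MontageError(
            f"recording {rec.recording_id!r} lacks required channels: "
            + ", ".join(missing)
        )
    keep = [c for c in montage.full_channels if c in resolved]
    order = [resolved[c] for c in keep]
    return rec.replace(channel_names=tuple(keep), data=rec.data[order])


def read_recording(
    path: str | Path,
    format: str | None = None,
    montage: MontageSpec = DEFAULT_MONTAGE,
    require: str = "analysis",
) -> Recording:
    """Read a recording (EDF or matrix format) and conform it to the montage.

    ``format`` is ``"edf"`` or ``"matrix"``; if None it is inferred from
    the file extension. Channels are renamed to canonical montage names and
    re-ordered to montage order; unrecognized channels are dropped with a
    warning; missing required channels raise :class:`MontageError`.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        rec = _read_edf(path)
    elif format == "matrix":
        rec = _read_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return conform_to_montage(rec, montage, require=require)


def select_analysis_channels(
    rec: Recording, montage: MontageSpec = DEFAULT_MONTAGE
) -> Recording:
    """Restrict a recording to the 16 lateral channels in pair-major order.

    The output order is left member of pair 1..8 followed by right member
    of pair 1..8, so pair ``i`` occupies rows ``(i, i + 8)``. Idempotent.
    """
    index = {normalize_channel_name(c): i for i, c in enumerate(rec.channel_names)}
    order = []
    missing = []
    for name in montage.analysis_channels:
        idx = index.get(normalize_channel_name(name))
        if idx is None:
            missing.append(name)
        else:
            order.append(idx)
    if missing:
        raise MontageError(
            f"recording {rec.recording_id!r} lacks analysis channels: "
            + ", ".join(missing)
        )
    return rec.replace(
        channel_names=tuple(montage.analysis_channels), data=rec.data[order]
    )
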