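"""Synthetic multichannel EEG with known seizures and known focus side.

Real long-term scalp EEG of focal epilepsy patients is rarely shareable,
so every stage of this pipeline is exercised on simulated recordings that
reproduce the statistical structure the method relies on:

* per-channel 1/f^alpha background noise (EEG spectra are approximately
  power-law; alpha = 1 by default) plus a 50 Hz power-line sinusoid;
* during each annotated seizure window, a rhythmic narrow-band oscillation
  (default 16-24 Hz, the beta range typical of rhythmic ictal discharges)
  added to all 16 lateral channels, with a Hann amplitude envelope and
  random phase so there is no detectable hard onset edge;
* the oscillation on the focus-side channels is scaled by the asymmetry
  factor gamma (default 1.5 in amplitude, i.e. 2.25x in energy), the
  energy excess the lateralization stage is designed to detect.

Recordings are sampled at 500 Hz on the 18-channel bipolar montage, with
seizure windows written as ictal annotations, the remainder interictal,
and the focus side stored as ground truth. All randomness derives from
``numpy.random.SeedSequence``, so a master seed reproduces a cohort
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import hann

from .errors import ConfigurationError
from .io import Interval, Recording
from .montage import DEFAULT_MONTAGE, MontageSpec, normalize_channel_name


@dataclass
class SynthConfig:
    """Parameters of one synthetic recording.

    ``background_amplitude_uv`` is the per-channel background RMS; with the
    default Hann-enveloped oscillation, ``ictal_amplitude_uv`` = 70 puts the
    in-window oscillation power at about the background power (0 dB SNR).
    """

    fs: float = 500.0
    duration_s: float = 600.0
    seizure_windows: tuple[tuple[float, float], ...] = ((256.0, 352.0),)
    focus_side: str = "right"
    asymmetry_factor: float = 1.5
    ictal_band_hz: tuple[float, float] = (16.0, 24.0)
    ictal_amplitude_uv: float = 70.0
    background_amplitude_uv: float = 30.0
    background_alpha: float = 1.0
    powerline_hz: float = 50.0
    powerline_amplitude_uv: float = 10.0
    seed: int = 0
    montage: MontageSpec = field(default_factory=lambda: DEFAULT_MONTAGE)

    def __post_init__(self) -> None:
        if self.focus_side not in ("left", "right"):
            raise ConfigurationError(f"unknown focus side {self.focus_side!r}")
        if self.asymmetry_factor < 1.0:
            raise ConfigurationError("asymmetry factor must be >= 1")
        windows = sorted(self.seizure_windows)
        for (s0, e0), (s1, e1) in zip(windows, windows[1:]):
            if s1 < e0:
                raise ConfigurationError("seizure windows must not overlap")
        for s, e in windows:
            if not (0 <= s < e <= self.duration_s):
                raise ConfigurationError(
                    f"seizure window ({s}, {e}) outside recording duration"
                )

    def replace(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


def _pink_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    weights = np.ones_like(freqs)
    nz = freqs > 0
    weights[nz] = freqs[nz] ** (-alpha / 2.0)
    weights[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spectrum * weights, n)
    return shaped / np.sqrt(np.mean(shaped**2))


def generate_recording(
    cfg: SynthConfig,
    subject_id: str = "synthetic",
    recording_id: str = "synthetic-rec",
) -> Recording:
    """Simulate one annotated recording with a known focus side."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    montage = cfg.montage
    channels = montage.full_channels
    data = np.empty((len(channels), n))

    for ch in range(len(channels)):
        bg = _pink_noise(n, cfg.background_alpha, rng) * cfg.background_amplitude_uv
        phase = rng.uniform(0, 2 * np.pi)
        bg += cfg.powerline_amplitude_uv * np.sin(
            2 * np.pi * cfg.powerline_hz * t + phase
        )
        data[ch] = bg

    left_set = {normalize_channel_name(l) for l, _ in montage.symmetric_pairs}
    right_set = {normalize_channel_name(r) for _, r in montage.symmetric_pairs}

    annotations: list[Interval] = []
    cursor = 0
    for start_s, end_s in sorted(cfg.seizure_windows):
        i0, i1 = int(round(start_s * cfg.fs)), int(round(end_s * cfg.fs))
        if i1 <= i0:
            continue
        envelope = hann(i1 - i0)
        f0 = rng.uniform(*cfg.ictal_band_hz)
        seg_t = t[i0:i1]
        for ch, name in enumerate(channels):
            key = normalize_channel_name(name)
            if key in left_set:
                gain = cfg.asymmetry_factor if cfg.focus_side == "left" else 1.0
            elif key in right_set:
                gain = cfg.asymmetry_factor if cfg.focus_side == "right" else 1.0
            else:
                continue  # midline channels stay background-only
            phase = rng.uniform(0, 2 * np.pi)
            data[ch, i0:i1] += (
                gain
                * cfg.ictal_amplitude_uv
                * envelope
                * np.sin(2 * np.pi * f0 * seg_t + phase)
            )
        if i0 > cursor:
            annotations.append(Interval(cursor, i0, "interictal"))
        annotations.append(Interval(i0, i1, "ictal"))
        cursor = i1
    if cursor < n:
        annotations.append(Interval(cursor, n, "interictal"))

    return Recording(
        subject_id=subject_id,
        recording_id=recording_id,
        fs=cfg.fs,
        channel_names=channels,
        data=data,
        annotations=annotations,
        true_laterality=cfg.focus_side,
    )


def generate_cohort(
    n_patients: int,
    recordings_per_patient: int | list[int],
    cfg: SynthConfig,
    seed: int,
    left_fraction: float = 28 / 76,
) -> list[Recording]:
    """Simulate a patient cohort; the focus side is fixed per patient.

    ``recordings_per_patient`` may be a single count or one count per
    patient. The number of left-focus patients is ``round(n_patients *
    left_fraction)``; side assignment is shuffled by the master seed.
    Per-recording seeds are derived from (master seed, patient index,
    recording index), so cohorts are reproducible yet recordings are
    statistically independent.
    """
    if n_patients < 1:
        raise ConfigurationError("need at least one patient")
    if isinstance(recordings_per_patient, int):
        counts = [recordings_per_patient] * n_patients
    else:
        counts = list(recordings_per_patient)
        if len(counts) != n_patients:
            raise ConfigurationError(
                "recordings_per_patient list must have one entry per patient"
            )
    master = np.random.default_rng(np.random.SeedSequence(seed))
    n_left = int(round(n_patients * left_fraction))
    sides = ["left"] * n_left + ["right"] * (n_patients - n_left)
    sides = [sides[i] for i in master.permutation(n_patients)]

    recordings = []
    for p, (side, n_rec) in enumerate(zip(sides, counts)):
        for r in range(n_rec):
            sub_seed = int(
                np.random.SeedSequence([seed, p, r]).generate_state(1)[0] % (2**31)
            )
            rec_cfg = cfg.replace(focus_side=side, seed=sub_seed)
            recordings.append(
                generate_recording(
                    rec_cfg,
                    subject_id=f"P{p:02d}",
                    recording_id=f"P{p:02d}-R{r}",
                )
            )
    return recordings
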