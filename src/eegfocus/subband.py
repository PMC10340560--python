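"""Dyadic wavelet subband decomposition and band-energy features.

Each epoch channel is decomposed with a nine-level discrete wavelet
transform (Daubechies db4, periodization boundary) at the 128 Hz analysis
rate, giving detail sets D1..D9 and the approximation A9. Because db4 is
orthonormal and periodization makes the transform square, the sum of
squared coefficients over {D1..D9, A9} equals the epoch's sum of squared
samples to machine precision, so coefficient energies are exactly band
energies.

The D2 set (16-32 Hz) is split once more with a single-level db4 DWT to
separate beta from gamma. In the coefficient domain of a detail subband the
frequency axis is mirrored by the decimation, so the *detail* child of D2
carries the lower half (beta, 16-24 Hz) and the *approximation* child the
upper half (gamma, 24-32 Hz); the mapping here is by physical frequency.

Named bands and their coefficient sets (analysis Nyquist 64 Hz):

====== ============== ==========================
band   range (Hz)     coefficient set(s)
====== ============== ==========================
Delta  0 - 4          D5 + D6 + D7 + D8 + D9 + A9
Theta  4 - 8          D4
Alpha  8 - 16         D3
Beta   16 - 24        low half of split(D2)
Gamma  24 - 32        high half of split(D2)
D1     32 - 64        D1
D2     16 - 32        D2
D5..D9 2-4 .. 0.125-0.25  each its own set
A9     0 - 0.125      A9
====== ============== ==========================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import ValidationError
from .preprocess import EpochSet

WAVELET = "db4"
MODE = "periodization"
LEVELS = 9
ANALYSIS_FS = 128.0

#: Coefficient-set keys produced by the decomposition. D2L/D2H are the
#: frequency-ordered halves of the single-level split of D2.
DYADIC_SETS = tuple(f"D{k}" for k in range(1, 10)) + ("A9",)
SPLIT_SETS = ("D2L", "D2H")


@dataclass(frozen=True)
class Band:
    name: str
    freq_range_hz: tuple[float, float]
    coefficient_sets: tuple[str, ...]


#: The 13 named bands, in report order.
BAND_TABLE: dict[str, Band] = {
    b.name: b
    for b in (
        Band("Delta", (0.0, 4.0), ("D5", "D6", "D7", "D8", "D9", "A9")),
        Band("Theta", (4.0, 8.0), ("D4",)),
        Band("Alpha", (8.0, 16.0), ("D3",)),
        Band("Beta", (16.0, 24.0), ("D2L",)),
        Band("Gamma", (24.0, 32.0), ("D2H",)),
        Band("D1", (32.0, 64.0), ("D1",)),
        Band("D2", (16.0, 32.0), ("D2",)),
        Band("D5", (2.0, 4.0), ("D5",)),
        Band("D6", (1.0, 2.0), ("D6",)),
        Band("D7", (0.5, 1.0), ("D7",)),
        Band("D8", (0.25, 0.5), ("D8",)),
        Band("D9", (0.125, 0.25), ("D9",)),
        Band("A9", (0.0, 0.125), ("A9",)),
    )
}

BAND_NAMES = tuple(BAND_TABLE)

#: Bands whose coefficient sets partition the whole dyadic tree.
PARTITION_BANDS = ("Delta", "Theta", "Alpha", "D2", "D1")


def _check_band(band: str) -> Band:
    try:
        return BAND_TABLE[band]
    except KeyError:
        raise KeyError(
            f"unknown band {band!r}; known bands: {', '.join(BAND_NAMES)}"
        ) from None


def _check_length(n: int) -> None:
    if n < 512 or (n & (n - 1)) != 0:
        raise ValidationError(
            f"epoch length must be a power of two >= 512, got {n}"
        )


def _decompose_sets(x: np.ndarray) -> dict[str, np.ndarray]:
    """Wavelet coefficient sets for an array whose last axis is time."""
    coeffs = pywt.wavedec(x, WAVELET, mode=MODE, level=LEVELS, axis=-1)
    names = ["A9"] + [f"D{k}" for k in range(LEVELS, 0, -1)]
    sets = dict(zip(names, coeffs))
    # Frequency axis is mirrored inside a detail subband: the approximation
    # child of D2 holds 24-32 Hz, the detail child 16-24 Hz.
    high, low = pywt.dwt(sets["D2"], WAVELET, mode=MODE, axis=-1)
    sets["D2L"] = low
    sets["D2H"] = high
    return sets


@dataclass
class SubbandDecomposition:
    """Per-channel map from coefficient-set name to coefficient array.

    ``sets[name]`` has shape (n_channels, n_coeffs); single-channel input
    keeps a leading axis of 1.
    """

    sets: dict[str, np.ndarray]
    wavelet: str = WAVELET
    mode: str = MODE
    levels: int = LEVELS
    fs: float = ANALYSIS_FS

    def set_energy(self, name: str) -> np.ndarray:
        """Sum of squared coefficients of one set, per channel."""
        return np.sum(self.sets[name] ** 2, axis=-1)


def dwt_tree(x: np.ndarray, fs: float) -> SubbandDecomposition:
    """Decompose epoch data into the nine-level db4 tree plus the D2 split.

    ``x`` is (n_samples,) or (n_channels, n_samples); ``fs`` must be the
    128 Hz analysis rate for the band names to mean their nominal ranges.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValidationError("dwt_tree expects 1-D or 2-D input")
    _check_length(x.shape[-1])
    if fs != ANALYSIS_FS:
        raise ValidationError(
            f"band table is defined at fs = {ANALYSIS_FS} Hz, got {fs}"
        )
    return SubbandDecomposition(sets=_decompose_sets(x), fs=fs)


def band_energy(dec: SubbandDecomposition, band: str) -> np.ndarray:
    """Per-channel energy of a named band (sum over its coefficient sets)."""
    b = _check_band(band)
    return sum(dec.set_energy(s) for s in b.coefficient_sets)


@dataclass
class FeatureMatrix:
    """Epochs x channels band-energy features for one band.

    ``X[i, c]`` is the energy (uV^2 * samples) of channel ``c`` in epoch
    ``i``; labels and origin are carried through from the epoch set.
    """

    band: str
    channel_names: tuple[str, ...]
    X: np.ndarray
    labels: np.ndarray
    origin: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.X.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if self.X.shape[1] != len(self.channel_names):
            raise ValidationError("one column per channel required")
        if len(self.labels) != self.X.shape[0]:
            raise ValidationError("one label per epoch required")
        if self.origin and len(self.origin) != self.X.shape[0]:
            raise ValidationError("origin must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            band=self.band,
            channel_names=self.channel_names,
            X=self.X[idx],
            labels=self.labels[idx],
            origin=[self.origin[i] for i in idx] if self.origin else [],
        )

    # -- persistence ------------------------------------------------------
    def to_csv(self, path) -> None:
        import pandas as pd

        frame = pd.DataFrame(self.X, columns=list(self.channel_names))
        frame.insert(0, "label", self.labels)
        if self.origin:
            frame.insert(1, "origin_recording", [o[0] for o in self.origin])
            frame.insert(2, "origin_start", [o[1] for o in self.origin])
        with open(path, "w") as fh:
            fh.write(f"# band: {self.band}\n")
            frame.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import pandas as pd

        with open(path) as fh:
            header = fh.readline()
            band = header.split(":", 1)[1].strip() if ":" in header else "Beta"
            frame = pd.read_csv(fh, float_precision="round_trip")
        origin = []
        if "origin_recording" in frame.columns:
            origin = list(
                zip(frame.pop("origin_recording"), frame.pop("origin_start").astype(int))
            )
        labels = frame.pop("label").to_numpy(dtype=object)
        return cls(
            band=band,
            channel_names=tuple(frame.columns),
            X=frame.to_numpy(dtype=np.float64),
            labels=labels,
            origin=origin,
        )


def extract_features(epochs: EpochSet, band: str) -> FeatureMatrix:
    """Band-energy feature matrix for all epochs of an epoch set."""
    b = _check_band(band)
    if epochs.n_epochs == 0:
        return FeatureMatrix(
            band=b.name,
            channel_names=epochs.channel_names,
            X=np.empty((0, epochs.n_channels)),
            labels=epochs.labels,
            origin=list(epochs.origin),
        )
    sets = _decompose_sets(epochs.epochs)  # (n_epochs, n_channels, n_coeffs)
    X = sum(np.sum(sets[s] ** 2, axis=-1) for s in b.coefficient_sets)
    return FeatureMatrix(
        band=b.name,
        channel_names=epochs.channel_names,
        X=X,
        labels=epochs.labels.copy(),
        origin=list(epochs.origin),
    )
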