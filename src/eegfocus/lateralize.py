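"""Epileptic-focus lateralization by hemispheric energy asymmetry.

Seizure activity raises signal energy on the focus side. For each of the
eight symmetric bipolar channel pairs, the asymmetry score is the ratio of
left to right energy over the ictal samples:

    A = sum(x_left[n]^2) / sum(x_right[n]^2)

A pair votes +1 when A > 1 (left excess) and -1 otherwise; note A == 1
falls to -1, consistent with the right-sided "else" branch of the decision
rule. The eight votes are summed: a positive total lateralizes the
recording to the left hemisphere, any other total (including zero) to the
right. A patient is called left-focus when strictly more of their
recordings lateralize left than right; ties again fall to the right.

Energies are pooled across a recording's ictal epochs (sum energies per
channel, then one ratio per pair) on the broadband preprocessed signal; a
per-epoch majority mode is available as an option. A pair whose right
channel has exactly zero pooled energy is degenerate and is excluded from
the vote rather than contributing an infinite score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, LateralizationError, ValidationError
from .io import Recording
from .metrics import MetricsReport
from .montage import DEFAULT_MONTAGE, MontageSpec
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

POSITIVE_SIDE = "left"


def asymmetry_score(xleft: np.ndarray, xright: np.ndarray) -> float:
    """Left/right energy ratio of two equal-length signal segments."""
    xleft = np.asarray(xleft, dtype=np.float64)
    xright = np.asarray(xright, dtype=np.float64)
    if xleft.shape != xright.shape:
        raise ValidationError(
            f"segment shapes differ: {xleft.shape} vs {xright.shape}"
        )
    e_right = float(np.sum(xright**2))
    if e_right == 0.0:
        raise DegenerateInputError("right-side segment has zero energy")
    return float(np.sum(xleft**2)) / e_right


def pair_vote(A: float) -> int:
    """+1 when the score exceeds 1 (left excess), else -1."""
    if A <= 0:
        raise ValidationError(f"asymmetry score must be positive, got {A}")
    return 1 if A > 1.0 else -1


@dataclass(frozen=True)
class PairResult:
    pair: tuple[str, str]
    score: float | None  # None when the pair is degenerate
    vote: int | None

    @property
    def excluded(self) -> bool:
        return self.score is None


@dataclass
class LateralityDecision:
    """Per-pair scores and votes plus the recording-level side."""

    recording_id: str
    pairs: list[PairResult]
    n_ictal_epochs: int

    @property
    def vote_sum(self) -> int:
        return sum(p.vote for p in self.pairs if p.vote is not None)

    @property
    def side(self) -> str:
        return "left" if self.vote_sum > 0 else "right"

    def to_dict(self) -> dict:
        return {
            "recording_id": self.recording_id,
            "n_ictal_epochs": self.n_ictal_epochs,
            "pairs": [
                {
                    "left": p.pair[0],
                    "right": p.pair[1],
                    "score": p.score,
                    "vote": p.vote,
                }
                for p in self.pairs
            ],
            "vote_sum": self.vote_sum,
            "side": self.side,
        }


@dataclass
class PatientDecision:
    """Majority of recording-level sides; a tie falls to the right."""

    subject_id: str
    recording_sides: list[str] = field(default_factory=list)

    @property
    def n_left(self) -> int:
        return sum(1 for s in self.recording_sides if s == "left")

    @property
    def n_right(self) -> int:
        return sum(1 for s in self.recording_sides if s == "right")

    @property
    def side(self) -> str:
        return "left" if self.n_left > self.n_right else "right"

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "recording_sides": list(self.recording_sides),
            "n_left": self.n_left,
            "n_right": self.n_right,
            "side": self.side,
        }


def _pooled_channel_energies(
    epochs: EpochSet, ictal_mask: np.ndarray
) -> np.ndarray:
    """Per-channel energy summed over the selected epochs."""
    selected = epochs.epochs[ictal_mask]
    return np.sum(selected**2, axis=(0, 2))


def recording_laterality(
    rec: Recording,
    ictal_epochs: EpochSet,
    montage: MontageSpec = DEFAULT_MONTAGE,
    labels: np.ndarray | None = None,
    mode: str = "pooled",
) -> LateralityDecision:
    """Lateralize one recording from its ictal epochs.

    ``ictal_epochs`` is the recording's segmented epoch set in canonical
    16-channel pair-major order; epochs labeled ictal (by ``labels`` if
    given, else by the epoch set's own labels) enter the computation.
    ``mode`` selects ``"pooled"`` (sum energies over all ictal epochs, one
    score per pair) or ``"per-epoch"`` (one vote per pair per epoch,
    majority across epochs).
    """
    if mode not in ("pooled", "per-epoch"):
        raise ValidationError(f"unknown lateralization mode {mode!r}")
    label_arr = np.asarray(
        ictal_epochs.labels if labels is None else labels, dtype=object
    )
    if len(label_arr) != ictal_epochs.n_epochs:
        raise ValidationError("one label per epoch required")
    if tuple(ictal_epochs.channel_names) != montage.analysis_channels:
        raise ValidationError(
            "epoch set must be in canonical 16-channel pair-major order"
        )
    mask = label_arr == "ictal"
    n_ictal = int(mask.sum())
    if n_ictal == 0:
        raise LateralizationError(
            f"recording {rec.recording_id!r} has no ictal epochs to lateralize"
        )

    pair_idx = montage.pair_indices()
    results: list[PairResult] = []
    if mode == "pooled":
        energies = _pooled_channel_energies(ictal_epochs, mask)
        for (li, ri), pair in zip(pair_idx, montage.symmetric_pairs):
            e_left, e_right = float(energies[li]), float(energies[ri])
            if e_right == 0.0:
                logger.warning(
                    "pair %s excluded: zero right-side energy (%s)",
                    pair, rec.recording_id,
                )
                results.append(PairResult(pair, None, None))
                continue
            score = e_left / e_right
            results.append(PairResult(pair, score, pair_vote(score)))
    else:
        per_epoch = np.sum(ictal_epochs.epochs[mask] ** 2, axis=2)  # (k, ch)
        for (li, ri), pair in zip(pair_idx, montage.symmetric_pairs):
            el, er = per_epoch[:, li], per_epoch[:, ri]
            valid = er > 0
            if not valid.any():
                results.append(PairResult(pair, None, None))
                continue
            votes = np.where(el[valid] / er[valid] > 1.0, 1, -1)
            majority = 1 if votes.sum() > 0 else -1
            score = float(np.sum(el[valid]) / np.sum(er[valid]))
            results.append(PairResult(pair, score, majority))

    return LateralityDecision(
        recording_id=rec.recording_id, pairs=results, n_ictal_epochs=n_ictal
    )


def patient_laterality(
    decisions: list[LateralityDecision], subject_id: str = "unknown"
) -> PatientDecision:
    """Majority vote over a patient's recording-level decisions."""
    if not decisions:
        raise LateralizationError("no recording decisions for patient")
    return PatientDecision(
        subject_id=subject_id, recording_sides=[d.side for d in decisions]
    )


def evaluate_lateralization(pred, gold) -> MetricsReport:
    """Confusion metrics over predicted sides, with left as positive."""
    gold_arr = np.asarray(gold, dtype=object)
    bad = set(gold_arr) - {"left", "right"}
    if bad:
        raise ValidationError(f"gold sides must be left/right, found {bad}")
    return MetricsReport.from_labels(pred, gold, positive_label=POSITIVE_SIDE)
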