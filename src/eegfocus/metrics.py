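"""Binary confusion-matrix metrics shared by both decision stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the accuracy / sensitivity / specificity trio.

    Sensitivity is the true-positive rate, specificity the true-negative
    rate; which label counts as positive is recorded in ``positive_label``
    (ictal for epoch classification, left for lateralization).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    positive_label: str

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "positive_label": self.positive_label,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    @classmethod
    def from_labels(cls, pred, gold, positive_label: str) -> "MetricsReport":
        pred = np.asarray(pred, dtype=object)
        gold = np.asarray(gold, dtype=object)
        if pred.shape != gold.shape:
            raise ValidationError(
                f"prediction length {pred.shape} != gold length {gold.shape}"
            )
        p = pred == positive_label
        g = gold == positive_label
        return cls(
            tp=int(np.sum(p & g)),
            fp=int(np.sum(p & ~g)),
            tn=int(np.sum(~p & ~g)),
            fn=int(np.sum(~p & g)),
            positive_label=positive_label,
        )
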