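"""Ictal/interictal epoch classification on band-energy features.

The classifier is a single-layer LSTM (128 hidden units) over the
per-epoch channel-energy vector, followed by a fully connected softmax
layer. Each epoch's 16 (or 18) energies are presented as a length-1
sequence. Before training, features are standardized per column with
training-split statistics; seizure data are heavily imbalanced (roughly
one ictal epoch per twelve interictal), so ictal rows of the *training*
split are duplicated to near balance — without this a classifier can reach
high accuracy by calling everything interictal.

Splitting is stratified by label at 70/15/15 train/validation/test, and
model selection keeps the parameters of the training epoch with the best
validation accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import network
from .errors import BalancingError, ConfigurationError, ValidationError
from .metrics import MetricsReport
from .subband import FeatureMatrix

POSITIVE = "ictal"
CLASSES = ("interictal", "ictal")  # index 1 = positive class


@dataclass
class LSTMConfig:
    """Architecture and training options for the epoch classifier."""

    input_size: int = 16
    hidden_units: int = 128
    n_classes: int = 2
    min_batch_size: int = 150
    max_epochs: int = 100
    initial_learning_rate: float = 0.001
    gradient_threshold: float = 2.0
    optimizer: str = "adam"
    sequence_len: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ConfigurationError("the classifier is binary (n_classes = 2)")
        for name in ("input_size", "hidden_units", "min_batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SplitSpec:
    """Stratified train/validation/test fractions."""

    train: float = 0.70
    val: float = 0.15
    test: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")
        if min(self.train, self.val, self.test) <= 0:
            raise ConfigurationError("split fractions must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Balancing and splitting
# ---------------------------------------------------------------------------

def balance_by_duplication(features: FeatureMatrix) -> FeatureMatrix:
    """Duplicate ictal rows whole to offset class imbalance.

    Each ictal row appears ``k = round(n_interictal / n_ictal)`` times in
    the output (at least once), bringing the class ratio into roughly
    [1/2, 2]. Interictal rows and all feature values are untouched. Apply
    to the training split only, after splitting, so no duplicate of a test
    row can leak into training.
    """
    labels = features.labels
    ictal_idx = np.flatnonzero(labels == "ictal")
    inter_idx = np.flatnonzero(labels == "interictal")
    if len(ictal_idx) == 0 or len(inter_idx) == 0:
        raise BalancingError(
            f"both classes required for balancing "
            f"(ictal={len(ictal_idx)}, interictal={len(inter_idx)})"
        )
    k = max(1, round(len(inter_idx) / len(ictal_idx)))
    if k == 1:
        return features
    extra = np.tile(ictal_idx, k - 1)
    order = np.concatenate([np.arange(features.n_epochs), extra])
    return features.subset(order)


def split_dataset(
    features: FeatureMatrix, spec: SplitSpec
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix]:
    """Disjoint stratified train/val/test partitions, shuffled by seed."""
    rng = np.random.default_rng(spec.seed)
    labels = features.labels
    classes = np.unique(labels.astype(str))
    for cls in classes:
        if np.sum(labels == cls) < 3:
            raise ValidationError(
                f"need at least 3 epochs of class {cls!r} to split"
            )
    parts: dict[str, list[np.ndarray]] = {"train": [], "val": [], "test": []}
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n = len(idx)
        n_train = int(round(spec.train * n))
        n_val = int(round(spec.val * n))
        n_train = min(n_train, n - 2)
        n_val = max(1, min(n_val, n - n_train - 1))
        parts["train"].append(idx[:n_train])
        parts["val"].append(idx[n_train : n_train + n_val])
        parts["test"].append(idx[n_train + n_val :])
    out = []
    for key in ("train", "val", "test"):
        idx = np.concatenate(parts[key])
        out.append(features.subset(rng.permutation(idx)))
    return tuple(out)


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

@dataclass
class Model:
    """A trained classifier: parameters, config, and feature scaling."""

    config: LSTMConfig
    params: dict[str, np.ndarray]
    mean: np.ndarray
    std: np.ndarray
    channel_names: tuple[str, ...]
    band: str
    history: dict[str, list[float]] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz file."""
        meta = {
            "config": self.config.to_dict(),
            "channel_names": list(self.channel_names),
            "band": self.band,
            "history": self.history,
        }
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        np.savez(
            path, mean=self.mean, std=self.std, meta=json.dumps(meta), **arrays
        )

    @classmethod
    def load(cls, path: str | Path) -> "Model":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            params = {
                k[len("param_"):]: archive[k]
                for k in archive.files
                if k.startswith("param_")
            }
            return cls(
                config=LSTMConfig(**meta["config"]),
                params=params,
                mean=archive["mean"],
                std=archive["std"],
                channel_names=tuple(meta["channel_names"]),
                band=meta["band"],
                history=meta["history"],
            )


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    return np.asarray([CLASSES.index(str(l)) for l in labels], dtype=np.int64)


def _to_sequences(X: np.ndarray, sequence_len: int) -> np.ndarray:
    # length-1 sequences by default; longer windows stack consecutive rows
    if sequence_len == 1:
        return X[:, None, :]
    n = X.shape[0] - sequence_len + 1
    if n <= 0:
        raise ValidationError("not enough epochs for the requested sequence length")
    return np.stack([X[i : i + sequence_len] for i in range(n)])


def train_classifier(
    train: FeatureMatrix, val: FeatureMatrix, cfg: LSTMConfig
) -> Model:
    """Train the LSTM on standardized band energies; keep the best epoch.

    The returned model holds the parameters of the training epoch with the
    highest validation accuracy, the per-epoch loss/accuracy history, and
    the standardization statistics computed on the training split.
    """
    if train.n_channels != cfg.input_size:
        raise ConfigurationError(
            f"feature dimension {train.n_channels} != input_size {cfg.input_size}"
        )
    if val.n_channels != cfg.input_size:
        raise ConfigurationError("validation feature dimension mismatch")

    mean = train.X.mean(axis=0)
    std = train.X.std(axis=0)
    std = np.where(std > 0, std, 1.0)

    Xtr = _to_sequences((train.X - mean) / std, cfg.sequence_len)
    ytr = _encode_labels(train.labels)[: Xtr.shape[0]]
    Xva = _to_sequences((val.X - mean) / std, cfg.sequence_len)
    yva = _encode_labels(val.labels)[: Xva.shape[0]]

    rng = np.random.default_rng(cfg.seed)
    params = network.init_params(cfg.input_size, cfg.hidden_units, cfg.n_classes, rng)
    opt = network.Adam(lr=cfg.initial_learning_rate)

    best_params = {k: v.copy() for k, v in params.items()}
    best_val = -1.0
    history: dict[str, list[float]] = {"loss": [], "val_accuracy": []}
    n = Xtr.shape[0]
    for _epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.min_batch_size):
            batch = perm[start : start + cfg.min_batch_size]
            probs, cache = network.forward(params, Xtr[batch])
            losses.append(network.cross_entropy(probs, ytr[batch]))
            grads = network.backward(params, cache, ytr[batch])
            grads = network.clip_gradients(grads, cfg.gradient_threshold)
            opt.step(params, grads)
        val_acc = network.accuracy(params, Xva, yva)
        history["loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_val:
            best_val = val_acc
            best_params = {k: v.copy() for k, v in params.items()}
    return Model(
        config=cfg,
        params=best_params,
        mean=mean,
        std=std,
        channel_names=train.channel_names,
        band=train.band,
        history=history,
    )


def predict_epochs(
    model: Model, features: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Predict per-epoch labels and class-score pairs (scores sum to 1)."""
    if features.n_channels != model.config.input_size:
        raise ConfigurationError(
            f"feature dimension {features.n_channels} != model input size "
            f"{model.config.input_size}"
        )
    if features.n_epochs == 0:
        return np.empty(0, dtype=object), np.empty((0, 2))
    X = _to_sequences(
        (features.X - model.mean) / model.std, model.config.sequence_len
    )
    scores = network.predict_proba(model.params, X)
    labels = np.asarray(
        [CLASSES[i] for i in scores.argmax(axis=1)], dtype=object
    )
    return labels, scores


def evaluate(pred, gold) -> MetricsReport:
    """Confusion metrics with ictal as the positive class."""
    return MetricsReport.from_labels(pred, gold, positive_label=POSITIVE)
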