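"""End-to-end orchestration: preprocess -> features -> classify -> lateralize.

``run_pipeline`` executes the full two-stage flow on a list of recordings
and returns a JSON-serializable report holding the epoch-classification
metrics, the per-recording and per-patient lateralization decisions, the
master seed, and a hash of the configuration. Given the same recordings,
configuration and seed, the report is identical byte for byte.

``band_sweep`` repeats the classification stage once per requested band
with shared splits and seeds, mirroring the design of a subband comparison
experiment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    LSTMConfig,
    SplitSpec,
    balance_by_duplication,
    evaluate,
    predict_epochs,
    split_dataset,
    train_classifier,
)
from .errors import ConfigurationError, LateralizationError
from .io import Recording, select_analysis_channels
from .lateralize import (
    evaluate_lateralization,
    patient_laterality,
    recording_laterality,
)
from .montage import DEFAULT_MONTAGE, MontageSpec
from .preprocess import (
    EpochSet,
    PreprocessConfig,
    concat_epochsets,
    preprocess_recording,
    segment_epochs,
)
from .subband import BAND_TABLE, FeatureMatrix, extract_features

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Nested configuration of the whole pipeline."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    lstm: LSTMConfig = field(default_factory=LSTMConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    band: str = "Beta"
    channel_mode: int = 16
    ictal_source: str = "gold"  # or "predicted"
    lateralization_mode: str = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band not in BAND_TABLE:
            raise ConfigurationError(
                f"unknown band {self.band!r}; known: {', '.join(BAND_TABLE)}"
            )
        if self.channel_mode not in (16, 18):
            raise ConfigurationError("channel_mode must be 16 or 18")
        if self.ictal_source not in ("gold", "predicted"):
            raise ConfigurationError("ictal_source must be 'gold' or 'predicted'")

    def to_dict(self) -> dict:
        return {
            "preprocess": self.preprocess.to_dict(),
            "lstm": self.lstm.to_dict(),
            "split": self.split.to_dict(),
            "band": self.band,
            "channel_mode": self.channel_mode,
            "ictal_source": self.ictal_source,
            "lateralization_mode": self.lateralization_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            preprocess=PreprocessConfig(**d.get("preprocess", {})),
            lstm=LSTMConfig(**d.get("lstm", {})),
            split=SplitSpec(**d.get("split", {})),
            band=d.get("band", "Beta"),
            channel_mode=d.get("channel_mode", 16),
            ictal_source=d.get("ictal_source", "gold"),
            lateralization_mode=d.get("lateralization_mode", "pooled"),
            seed=d.get("seed", 0),
        )

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def derived_seeds(self) -> tuple[int, int]:
        """(split seed, training seed) derived from the master seed."""
        state = np.random.SeedSequence([self.seed, 0xE9]).generate_state(2)
        return int(state[0] % (2**31)), int(state[1] % (2**31))


@dataclass
class PreparedRecording:
    """A recording after preprocessing and segmentation."""

    recording: Recording  # preprocessed, at the analysis rate
    lateral_epochs: EpochSet  # 16-channel, pair-major
    feature_epochs: EpochSet  # 16 or 18 channels per channel_mode


def prepare_recordings(
    recordings: list[Recording],
    cfg: PipelineConfig,
    montage: MontageSpec = DEFAULT_MONTAGE,
) -> list[PreparedRecording]:
    """Filter, resample, and segment every recording once."""
    prepared = []
    for rec in recordings:
        proc = preprocess_recording(rec, cfg.preprocess)
        lateral = select_analysis_channels(proc, montage)
        lateral_epochs = segment_epochs(lateral, cfg.preprocess)
        if cfg.channel_mode == 16:
            feature_epochs = lateral_epochs
        else:
            feature_epochs = segment_epochs(proc, cfg.preprocess)
        prepared.append(PreparedRecording(lateral, lateral_epochs, feature_epochs))
    return prepared


def _classification_stage(
    prepared: list[PreparedRecording], cfg: PipelineConfig, band: str
) -> tuple[dict, "Model", FeatureMatrix]:
    from .classify import Model  # noqa: F401  (type only)

    features = concat_epochsets([p.feature_epochs for p in prepared])
    all_features = extract_features(features, band)
    split_seed, train_seed = cfg.derived_seeds()
    split = SplitSpec(
        train=cfg.split.train, val=cfg.split.val, test=cfg.split.test, seed=split_seed
    )
    train, val, test = split_dataset(all_features, split)
    train_bal = balance_by_duplication(train)
    lstm = LSTMConfig(**{**cfg.lstm.to_dict(), "seed": train_seed})
    model = train_classifier(train_bal, val, lstm)

    report = {}
    for name, part in (("training", train_bal), ("validation", val), ("test", test)):
        pred, _ = predict_epochs(model, part)
        report[name] = evaluate(pred, part.labels).to_dict()
    report["n_epochs"] = {
        "total": all_features.n_epochs,
        "train": train.n_epochs,
        "train_balanced": train_bal.n_epochs,
        "val": val.n_epochs,
        "test": test.n_epochs,
    }
    return report, model, all_features


def _lateralization_stage(
    prepared: list[PreparedRecording],
    cfg: PipelineConfig,
    model,
    montage: MontageSpec = DEFAULT_MONTAGE,
) -> dict:
    decisions = []
    skipped = []
    by_patient: dict[str, list] = {}
    truth_rec, pred_rec = [], []
    for p in prepared:
        rec = p.recording
        if cfg.ictal_source == "predicted":
            feats = extract_features(p.feature_epochs, cfg.band)
            labels, _ = predict_epochs(model, feats)
        else:
            labels = p.lateral_epochs.labels
        try:
            decision = recording_laterality(
                rec,
                p.lateral_epochs,
                montage,
                labels=labels,
                mode=cfg.lateralization_mode,
            )
        except LateralizationError:
            logger.warning(
                "recording %s: no ictal epochs (%s source); skipping",
                rec.recording_id, cfg.ictal_source,
            )
            skipped.append(rec.recording_id)
            continue
        decisions.append(decision)
        by_patient.setdefault(rec.subject_id, []).append((decision, rec))
        if rec.true_laterality is not None:
            truth_rec.append(rec.true_laterality)
            pred_rec.append(decision.side)

    report: dict = {
        "decisions": [d.to_dict() for d in decisions],
        "skipped_recordings": skipped,
    }
    if truth_rec:
        report["recording_level"] = evaluate_lateralization(
            pred_rec, truth_rec
        ).to_dict()

    patients = []
    truth_pat, pred_pat = [], []
    for subject, items in sorted(by_patient.items()):
        pdec = patient_laterality([d for d, _ in items], subject_id=subject)
        patients.append(pdec.to_dict())
        truths = {r.true_laterality for _, r in items if r.true_laterality}
        if len(truths) == 1:
            truth_pat.append(next(iter(truths)))
            pred_pat.append(pdec.side)
    report["patients"] = patients
    if truth_pat:
        report["patient_level"] = evaluate_lateralization(
            pred_pat, truth_pat
        ).to_dict()
    return report


def run_pipeline(
    recordings: list[Recording],
    cfg: PipelineConfig,
    montage: MontageSpec = DEFAULT_MONTAGE,
) -> dict:
    """Execute preprocess -> features -> classify -> lateralize.

    Returns a JSON-serializable report; identical inputs, configuration
    and seed yield an identical report.
    """
    prepared = prepare_recordings(recordings, cfg, montage)
    clf_report, model, _ = _classification_stage(prepared, cfg, cfg.band)
    lat_report = _lateralization_stage(prepared, cfg, model, montage)
    return {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "band": cfg.band,
        "channel_mode": cfg.channel_mode,
        "n_recordings": len(recordings),
        "classification": clf_report,
        "lateralization": lat_report,
    }


def report_to_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a pipeline report."""
    return json.dumps(report, sort_keys=True, indent=2)


def band_sweep(
    recordings: list[Recording],
    cfg: PipelineConfig,
    bands: list[str],
    montage: MontageSpec = DEFAULT_MONTAGE,
) -> pd.DataFrame:
    """Train/evaluate one classifier per band with shared splits and seeds.

    Returns a table with one row per band: validation, test, and training
    accuracy.
    """
    if not bands:
        raise ConfigurationError("band_sweep needs at least one band")
    for band in bands:
        if band not in BAND_TABLE:
            raise ConfigurationError(f"unknown band {band!r}")
    prepared = prepare_recordings(recordings, cfg, montage)
    rows = []
    for band in bands:
        clf_report, _, _ = _classification_stage(prepared, cfg, band)
        rows.append(
            {
                "band": band,
                "validation_accuracy": clf_report["validation"]["accuracy"],
                "test_accuracy": clf_report["test"]["accuracy"],
                "training_accuracy": clf_report["training"]["accuracy"],
            }
        )
    return pd.DataFrame(rows)
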