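"""Shared fixtures: small synthetic recordings and derived feature sets.

Everything is generated at test time from fixed seeds; recordings are kept
short (a few minutes at 500 Hz) so the whole suite runs in minutes on one
CPU core.
"""

from __future__ import annotations

import numpy as np
import pytest

import eegfocus as ef
from eegfocus import PreprocessConfig, SynthConfig
from eegfocus.preprocess import concat_epochsets


@pytest.fixture(scope="session")
def preprocess_cfg() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    # 352 s with one 96 s seizure -> 11 analysis epochs, 3 of them ictal
    return SynthConfig(duration_s=352.0, seizure_windows=((128.0, 224.0),))


@pytest.fixture(scope="session")
def left_recording(synth_cfg):
    cfg = synth_cfg.replace(focus_side="left", seed=42)
    return ef.generate_recording(cfg, subject_id="P-left", recording_id="P-left-R0")


@pytest.fixture(scope="session")
def small_cohort(synth_cfg):
    """Six patients x two recordings, mixed focus sides."""
    return ef.generate_cohort(6, 2, synth_cfg, seed=7)


@pytest.fixture(scope="session")
def cohort_features(small_cohort, preprocess_cfg):
    """Beta-band features of the small cohort (canonical 16 channels)."""
    sets = []
    for rec in small_cohort:
        proc = ef.preprocess_recording(ef.select_analysis_channels(rec), preprocess_cfg)
        sets.append(ef.segment_epochs(proc, preprocess_cfg))
    return ef.extract_features(concat_epochsets(sets), "Beta")


@pytest.fixture(scope="session")
def prepared_left(left_recording, preprocess_cfg):
    """(preprocessed 16-channel recording, its epoch set) for the left case."""
    proc = ef.preprocess_recording(
        ef.select_analysis_channels(left_recording), preprocess_cfg
    )
    return proc, ef.segment_epochs(proc, preprocess_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
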