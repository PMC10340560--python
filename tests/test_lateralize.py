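"""Asymmetry score, pair/recording/patient voting, and their evaluation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegfocus as ef
from eegfocus.io import Recording
from eegfocus.preprocess import EpochSet

FS = 128.0
L = 512


class TestAsymmetryScore:
    def test_identical_segments_score_one(self, rng):
        x = rng.standard_normal(1000)
        assert ef.asymmetry_score(x, x) == pytest.approx(1.0, rel=1e-12)

    def test_doubled_left_scores_four(self, rng):
        x = rng.standard_normal(1000)
        assert ef.asymmetry_score(2 * x, x) == pytest.approx(4.0, rel=1e-12)

    def test_zero_right_energy_is_degenerate(self, rng):
        with pytest.raises(ef.DegenerateInputError):
            ef.asymmetry_score(rng.standard_normal(100), np.zeros(100))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ef.ValidationError):
            ef.asymmetry_score(rng.standard_normal(10), rng.standard_normal(11))

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 2**20), scale=st.floats(0.01, 100.0))
    def test_swap_inverts_and_common_scale_cancels(self, seed, scale):
        r = np.random.default_rng(seed)
        xl = r.standard_normal(64) + 0.1
        xr = r.standard_normal(64) + 0.1
        a = ef.asymmetry_score(xl, xr)
        assert ef.asymmetry_score(xr, xl) == pytest.approx(1 / a, rel=1e-12)
        assert ef.asymmetry_score(scale * xl, scale * xr) == pytest.approx(
            a, rel=1e-9
        )
        if not np.isclose(a, 1.0):
            assert ef.pair_vote(a) == -ef.pair_vote(1 / a)


class TestPairVote:
    @pytest.mark.parametrize("score,vote", [(1.5, 1), (0.5, -1), (1.0, -1)])
    def test_threshold_at_one_with_right_biased_boundary(self, score, vote):
        assert ef.pair_vote(score) == vote

    def test_nonpositive_score_rejected(self):
        with pytest.raises(ef.ValidationError):
            ef.pair_vote(0.0)


def _epochs_with_pair_amplitudes(left_amps, right_amps, labels=("ictal",)):
    """One epoch set whose pair energies are fixed by constant amplitudes."""
    n = len(labels)
    data = np.ones((n, 16, L))
    for i in range(8):
        data[:, i, :] = left_amps[i]
        data[:, i + 8, :] = right_amps[i]
    return EpochSet(
        fs=FS,
        epoch_len=L,
        channel_names=ef.DEFAULT_MONTAGE.analysis_channels,
        epochs=data,
        labels=np.array(labels, dtype=object),
        origin=[("R", i * L) for i in range(n)],
    )


def _dummy_recording():
    return Recording(
        subject_id="S",
        recording_id="R",
        fs=FS,
        channel_names=ef.DEFAULT_MONTAGE.analysis_channels,
        data=np.zeros((16, L)),
    )


class TestRecordingLaterality:
    def test_all_left_votes_give_left(self):
        es = _epochs_with_pair_amplitudes([2.0] * 8, [1.0] * 8)
        d = ef.recording_laterality(_dummy_recording(), es)
        assert d.vote_sum == 8 and d.side == "left"
        for p in d.pairs:
            assert p.score == pytest.approx(4.0)

    def test_tied_votes_fall_to_right(self):
        es = _epochs_with_pair_amplitudes(
            [2.0] * 4 + [1.0] * 4, [1.0] * 4 + [2.0] * 4
        )
        d = ef.recording_laterality(_dummy_recording(), es)
        assert d.vote_sum == 0 and d.side == "right"

    def test_scaled_left_channels_lateralize_left(self, rng):
        """Brute-force check on a constructed segment: left members 1.5x
        the right members in every pair."""
        base = rng.standard_normal((8, L))
        data = np.concatenate([1.5 * base, base], axis=0)[None]
        es = EpochSet(
            fs=FS,
            epoch_len=L,
            channel_names=ef.DEFAULT_MONTAGE.analysis_channels,
            epochs=data,
            labels=np.array(["ictal"], dtype=object),
            origin=[("R", 0)],
        )
        d = ef.recording_laterality(_dummy_recording(), es)
        assert d.side == "left"
        for p in d.pairs:
            assert p.score == pytest.approx(2.25, rel=1e-12)

    def test_exhaustive_vote_patterns_match_sign_rule(self):
        """All 2^8 pair-vote patterns: the recording side equals the sign
        rule (vote sum > 0 -> left, else right)."""
        rec = _dummy_recording()
        for pattern in range(256):
            votes = [1 if pattern & (1 << i) else -1 for i in range(8)]
            left = [2.0 if v == 1 else 0.5 for v in votes]
            es = _epochs_with_pair_amplitudes(left, [1.0] * 8)
            d = ef.recording_laterality(rec, es)
            assert [p.vote for p in d.pairs] == votes
            assert d.vote_sum == sum(votes)
            assert d.side == ("left" if sum(votes) > 0 else "right")

    def test_degenerate_pair_excluded_from_vote(self):
        left = [2.0] * 8
        right = [1.0] * 8
        es = _epochs_with_pair_amplitudes(left, right)
        es.epochs[:, 8 + 3, :] = 0.0  # flat right channel of pair 4
        d = ef.recording_laterality(_dummy_recording(), es)
        assert d.pairs[3].excluded
        assert d.vote_sum == 7
        assert d.side == "left"

    def test_no_ictal_epochs_raises(self):
        es = _epochs_with_pair_amplitudes([1.0] * 8, [1.0] * 8, labels=("interictal",))
        with pytest.raises(ef.LateralizationError):
            ef.recording_laterality(_dummy_recording(), es)

    def test_per_epoch_mode_agrees_on_consistent_data(self):
        es = _epochs_with_pair_amplitudes(
            [2.0] * 8, [1.0] * 8, labels=("ictal", "ictal")
        )
        pooled = ef.recording_laterality(_dummy_recording(), es, mode="pooled")
        per_epoch = ef.recording_laterality(_dummy_recording(), es, mode="per-epoch")
        assert pooled.side == per_epoch.side == "left"


class TestPatientLaterality:
    def _decision(self, side):
        es = _epochs_with_pair_amplitudes(
            [2.0 if side == "left" else 0.5] * 8, [1.0] * 8
        )
        return ef.recording_laterality(_dummy_recording(), es)

    def test_majority_left(self):
        d = ef.patient_laterality(
            [self._decision(s) for s in ("left", "left", "right")]
        )
        assert d.side == "left" and d.n_left == 2

    def test_tie_falls_to_right(self):
        d = ef.patient_laterality([self._decision(s) for s in ("left", "right")])
        assert d.side == "right"

    def test_single_recording(self):
        assert ef.patient_laterality([self._decision("right")]).side == "right"

    def test_empty_list_rejected(self):
        with pytest.raises(ef.LateralizationError):
            ef.patient_laterality([])


class TestEvaluateLateralization:
    def test_perfect(self):
        gold = np.array(["left", "right"], dtype=object)
        m = ef.evaluate_lateralization(gold, gold)
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    def test_cohort_counts(self):
        """28 left all correct, 45 of 48 right correct: accuracy 73/76,
        sensitivity 1 (left positive), specificity 45/48."""
        gold = np.array(["left"] * 28 + ["right"] * 48, dtype=object)
        pred = gold.copy()
        pred[28:31] = "left"  # three right recordings called left
        m = ef.evaluate_lateralization(pred, gold)
        assert m.accuracy == pytest.approx(73 / 76)
        assert m.sensitivity == 1.0
        assert m.specificity == pytest.approx(45 / 48)

    def test_all_right_prediction(self):
        gold = np.array(["left"] * 28 + ["right"] * 48, dtype=object)
        pred = np.array(["right"] * 76, dtype=object)
        m = ef.evaluate_lateralization(pred, gold)
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_bad_gold_label_rejected(self):
        with pytest.raises(ef.ValidationError):
            ef.evaluate_lateralization(
                np.array(["left"], object), np.array(["bilateral"], object)
            )
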