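"""Balancing, splitting, training, and evaluation of the epoch classifier."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegfocus as ef
from eegfocus.classify import CLASSES
from eegfocus.subband import FeatureMatrix


def _features(n_ictal, n_interictal, n_channels=16, seed=0, separation=0.0):
    """Feature matrix with Gaussian classes ``separation`` apart."""
    rng = np.random.default_rng(seed)
    Xi = rng.standard_normal((n_ictal, n_channels)) + separation
    Xn = rng.standard_normal((n_interictal, n_channels))
    X = np.concatenate([Xi, Xn])
    labels = np.array(
        ["ictal"] * n_ictal + ["interictal"] * n_interictal, dtype=object
    )
    perm = rng.permutation(len(labels))
    return FeatureMatrix(
        band="Beta",
        channel_names=ef.DEFAULT_MONTAGE.analysis_channels[:n_channels],
        X=X[perm],
        labels=labels[perm],
        origin=[("R", i) for i in range(len(labels))],
    )


def _nearest_mean_accuracy(train, test):
    """Independent separability oracle: classify by distance to class mean."""
    means = {
        c: train.X[train.labels == c].mean(axis=0) for c in ("ictal", "interictal")
    }
    pred = [
        min(means, key=lambda c: np.linalg.norm(x - means[c])) for x in test.X
    ]
    return float(np.mean(np.asarray(pred, object) == test.labels))


class TestBalancing:
    def test_duplication_factor_from_study_scale_imbalance(self):
        """A 926:10652 ictal:interictal imbalance balances with k = 12 to a
        class ratio inside [1/2, 2]."""
        fm = _features(926, 10_652, n_channels=2, seed=1)
        out = ef.balance_by_duplication(fm)
        n_ictal = int(np.sum(out.labels == "ictal"))
        n_inter = int(np.sum(out.labels == "interictal"))
        assert n_ictal == 926 * 12
        assert n_inter == 10_652
        assert 0.5 <= n_inter / n_ictal <= 2.0

    def test_interictal_rows_and_values_untouched(self):
        fm = _features(5, 60, seed=2)
        out = ef.balance_by_duplication(fm)
        inter_before = fm.X[fm.labels == "interictal"]
        inter_after = out.X[out.labels == "interictal"]
        np.testing.assert_array_equal(
            np.sort(inter_after, axis=0), np.sort(inter_before, axis=0)
        )
        # every balanced row is an exact copy of an input row
        assert {tuple(r) for r in out.X} <= {tuple(r) for r in fm.X}

    def test_already_balanced_unchanged(self):
        fm = _features(30, 30, seed=3)
        out = ef.balance_by_duplication(fm)
        assert out.n_epochs == fm.n_epochs
        np.testing.assert_array_equal(out.X, fm.X)

    def test_absent_class_raises(self):
        fm = _features(0, 30, seed=4)
        with pytest.raises(ef.BalancingError):
            ef.balance_by_duplication(fm)


class TestSplit:
    def test_fractions(self):
        fm = _features(500, 500, n_channels=2, seed=5)
        tr, va, te = ef.split_dataset(fm, ef.SplitSpec(seed=0))
        assert (tr.n_epochs, va.n_epochs, te.n_epochs) == (700, 150, 150)
        # stratification: both classes at the split fractions
        assert np.sum(tr.labels == "ictal") == 350

    def test_partitions_disjoint_and_exhaustive(self):
        fm = _features(40, 60, n_channels=2, seed=6)
        tr, va, te = ef.split_dataset(fm, ef.SplitSpec(seed=1))
        origins = [o for part in (tr, va, te) for o in part.origin]
        assert len(origins) == 100
        assert len(set(origins)) == 100

    def test_same_seed_reproduces_partition(self):
        fm = _features(40, 60, seed=7)
        a = ef.split_dataset(fm, ef.SplitSpec(seed=3))
        b = ef.split_dataset(fm, ef.SplitSpec(seed=3))
        for pa, pb in zip(a, b):
            assert pa.origin == pb.origin

    def test_different_seed_changes_partition_not_sizes(self):
        fm = _features(40, 60, seed=8)
        a = ef.split_dataset(fm, ef.SplitSpec(seed=3))
        b = ef.split_dataset(fm, ef.SplitSpec(seed=4))
        assert [p.n_epochs for p in a] == [p.n_epochs for p in b]
        assert a[0].origin != b[0].origin

    def test_too_few_epochs_rejected(self):
        fm = _features(2, 60, seed=9)
        with pytest.raises(ef.ValidationError):
            ef.split_dataset(fm, ef.SplitSpec(seed=0))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ef.ConfigurationError):
            ef.SplitSpec(train=0.75, val=0.15, test=0.15)


@pytest.fixture(scope="module")
def separable_task():
    fm = _features(150, 150, seed=10, separation=2.0)
    return ef.split_dataset(fm, ef.SplitSpec(seed=0))


@pytest.fixture(scope="module")
def trained(separable_task):
    tr, va, _ = separable_task
    cfg = ef.LSTMConfig(seed=0, max_epochs=40)
    return ef.train_classifier(ef.balance_by_duplication(tr), va, cfg)


class TestTraining:
    def test_validation_accuracy_on_separable_task(self, separable_task, trained):
        tr, va, _ = separable_task
        # the task really is separable: nearest-class-mean oracle agrees
        assert _nearest_mean_accuracy(tr, va) >= 0.95
        assert max(trained.history["val_accuracy"]) >= 0.95

    def test_training_set_accuracy(self, separable_task, trained):
        tr, _, _ = separable_task
        pred, _ = ef.predict_epochs(trained, tr)
        assert np.mean(pred == tr.labels) >= 0.95

    def test_scores_sum_to_one(self, separable_task, trained):
        _, _, te = separable_task
        _, scores = ef.predict_epochs(trained, te)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_seed_identical_training(self, separable_task):
        tr, va, _ = separable_task
        cfg = ef.LSTMConfig(seed=5, max_epochs=5)
        m1 = ef.train_classifier(tr, va, cfg)
        m2 = ef.train_classifier(tr, va, cfg)
        assert m1.history == m2.history
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_dimension_mismatch_rejected(self, separable_task, trained):
        bad = _features(10, 10, n_channels=4, seed=11)
        with pytest.raises(ef.ConfigurationError):
            ef.predict_epochs(trained, bad)
        tr, va, _ = separable_task
        with pytest.raises(ef.ConfigurationError):
            ef.train_classifier(bad, va, ef.LSTMConfig(seed=0))

    def test_empty_features_empty_predictions(self, trained):
        empty = _features(0, 0, seed=12)
        labels, scores = ef.predict_epochs(trained, empty)
        assert len(labels) == 0 and scores.shape == (0, 2)

    def test_model_round_trip(self, separable_task, trained, tmp_path):
        _, _, te = separable_task
        path = tmp_path / "model.npz"
        trained.save(path)
        back = ef.Model.load(path)
        p1, s1 = ef.predict_epochs(trained, te)
        p2, s2 = ef.predict_epochs(back, te)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(s1, s2)


class TestEvaluate:
    def test_perfect_prediction(self):
        gold = np.array(["ictal", "interictal", "ictal"], dtype=object)
        m = ef.evaluate(gold, gold)
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    def test_all_interictal_on_one_to_twelve_data(self):
        """The degenerate majority-class strategy: high accuracy, zero
        sensitivity — exactly what training-set balancing guards against."""
        gold = np.array(["ictal"] * 1 + ["interictal"] * 12, dtype=object)
        pred = np.array(["interictal"] * 13, dtype=object)
        m = ef.evaluate(pred, gold)
        assert m.accuracy == pytest.approx(12 / 13)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0

    def test_complement_prediction_zero_accuracy(self):
        gold = np.array(["ictal", "interictal"], dtype=object)
        pred = np.array(["interictal", "ictal"], dtype=object)
        assert ef.evaluate(pred, gold).accuracy == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ef.ValidationError):
            ef.evaluate(np.array(["ictal"]), np.array(["ictal", "ictal"]))

    @settings(deadline=None, max_examples=30)
    @given(
        labels=st.lists(
            st.tuples(st.sampled_from(CLASSES), st.sampled_from(CLASSES)),
            min_size=1,
            max_size=40,
        ),
        seed=st.integers(0, 2**16),
    )
    def test_invariant_to_joint_permutation(self, labels, seed):
        pred = np.array([p for p, _ in labels], dtype=object)
        gold = np.array([g for _, g in labels], dtype=object)
        perm = np.random.default_rng(seed).permutation(len(labels))
        before = ef.evaluate(pred, gold).to_dict()
        after = ef.evaluate(pred[perm], gold[perm]).to_dict()
        assert before.pop("positive_label") == after.pop("positive_label")
        assert after == pytest.approx(before, nan_ok=True)
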