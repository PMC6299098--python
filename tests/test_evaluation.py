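import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import matthews_corrcoef, roc_auc_score

import phogly as pg
from phogly.evaluation import ConfusionCounts, _mean_metrics
from conftest import random_feature_dataset


def oracle_metrics(tp, fn, tn, fp):
    """Independent re-coding of the six threshold-metric formulas."""
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tn + tp) / (fn + fp + tn + tp)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tn * tp) - (fn * fp)) / math.sqrt(den) if den else 0.0
    fmeas = (2 * tp) / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return sens, spec, math.sqrt(sens * spec), acc, mcc, fmeas


def oracle_auc(labels, scores):
    """Brute-force over all positive-negative pairs; ties count one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_mixed_example(self):
        c = pg.confusion(np.array([1, 1, 0, 0]), np.array([1, 0, 0, 1]))
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_and_inverted(self):
        labels = np.array([1, 0, 1, 0])
        perfect = pg.confusion(labels, labels)
        assert perfect.fn == perfect.fp == 0
        inverted = pg.confusion(labels, 1 - labels)
        assert inverted.tp == inverted.tn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pg.confusion(np.array([1]), np.array([1, 0]))


class TestMetricFormulas:
    def test_perfect_classifier(self):
        m = pg.compute_metrics(ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        for name in ("sensitivity", "specificity", "gmean", "accuracy",
                     "mcc", "fmeasure"):
            assert getattr(m, name) == pytest.approx(1.0)

    def test_hand_worked_table(self):
        m = pg.compute_metrics(ConfusionCounts(tp=3, fn=1, tn=4, fp=2))
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(4 / 6)
        assert m.accuracy == pytest.approx(0.7)
        assert m.mcc == pytest.approx(10 / math.sqrt(600))
        assert m.fmeasure == pytest.approx(6 / 9)
        assert m.gmean == pytest.approx(math.sqrt(0.75 * 4 / 6))

    def test_degenerate_no_positives_sentinel(self):
        m = pg.compute_metrics(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert m.sensitivity == 0.0
        assert m.mcc == 0.0

    def test_oracle_agreement_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fn, tn, fp = rng.integers(0, 60, size=4)
            if tp + fn + tn + fp == 0:
                continue
            m = pg.compute_metrics(ConfusionCounts(int(tp), int(fn), int(tn), int(fp)))
            sens, spec, gmean, acc, mcc, fmeas = oracle_metrics(tp, fn, tn, fp)
            assert abs(m.sensitivity - sens) < 1e-12
            assert abs(m.specificity - spec) < 1e-12
            assert abs(m.gmean - gmean) < 1e-12
            assert abs(m.accuracy - acc) < 1e-12
            assert abs(m.mcc - mcc) < 1e-12
            assert abs(m.fmeasure - fmeas) < 1e-12
            assert m.gmean**2 == pytest.approx(m.sensitivity * m.specificity)

    def test_mcc_cross_checked_against_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            labels = rng.integers(0, 2, size=30)
            preds = rng.integers(0, 2, size=30)
            if len(set(labels)) < 2 or len(set(preds)) < 2:
                continue
            m = pg.compute_metrics(pg.confusion(labels, preds))
            assert m.mcc == pytest.approx(matthews_corrcoef(labels, preds), abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        assert pg.roc_auc(np.array([1, 0]), np.array([0.9, 0.1])) == 1.0

    def test_all_ties_give_half(self):
        assert pg.roc_auc(np.array([1, 0, 1, 0]), np.full(4, 0.3)) == 0.5

    def test_three_of_four_pairs(self):
        auc = pg.roc_auc(np.array([1, 1, 0, 0]), np.array([0.8, 0.4, 0.6, 0.2]))
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pg.roc_auc(np.ones(3, dtype=int), np.array([0.1, 0.2, 0.3]))

    def test_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            auc = pg.roc_auc(labels, scores)
            assert auc == pytest.approx(oracle_auc(labels, scores), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        scores = rng.random(8)
        base = pg.roc_auc(labels, scores)
        assert pg.roc_auc(labels, np.exp(3 * scores)) == pytest.approx(base)
        assert pg.roc_auc(labels, 2 * scores - 5) == pytest.approx(base)

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(3)
        labels = np.array([1, 0, 1, 0, 0, 1])
        scores = rng.permutation(np.arange(6)) / 6.0  # tie-free
        assert pg.roc_auc(labels, scores) + pg.roc_auc(labels, -scores) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def cv_result_and_dataset(null_bundle):
    ds = pg.build_dataset(
        null_bundle.proteins, null_bundle.tables, null_bundle.annotations, w=2
    )
    result = pg.target_cross_validate(
        ds, folds=5, config=pg.MLPConfig(epochs=30, seed=0), seed=0
    )
    return result, ds


class TestTargetCrossValidation:
    def test_partition_law(self, cv_result_and_dataset):
        result, ds = cv_result_and_dataset
        assert len(result.folds) == 5
        all_val = np.concatenate([f.val_indices for f in result.folds])
        assert sorted(all_val.tolist()) == list(range(len(ds)))

    def test_mean_is_arithmetic_mean_of_folds(self, cv_result_and_dataset):
        result, _ = cv_result_and_dataset
        for name in ("gmean", "auc", "accuracy", "mcc"):
            per_fold = [getattr(f.metrics, name) for f in result.folds]
            assert getattr(result.mean, name) == pytest.approx(np.mean(per_fold))
        recomputed = _mean_metrics(result.fold_metrics)
        assert recomputed.as_dict() == pytest.approx(result.mean.as_dict())

    def test_leakage_audit_ids(self, cv_result_and_dataset):
        """Validation instances never enter training or cleaning structures."""
        result, ds = cv_result_and_dataset
        for f in result.folds:
            val_ids = {ds.ids[i] for i in f.val_indices}
            removed = set(f.cleaning.removed_ids)
            assert not (val_ids & removed)
            assert f.train_pos_after == f.train_pos_before

    def test_training_rebalanced_to_ratio(self, cv_result_and_dataset):
        result, _ = cv_result_and_dataset
        for f in result.folds:
            assert f.cleaning.n_neg_after <= 2.0 * f.cleaning.n_pos

    def test_deterministic_given_seed(self, null_bundle):
        ds = pg.build_dataset(
            null_bundle.proteins, null_bundle.tables, null_bundle.annotations, w=2
        )
        cfg = pg.MLPConfig(epochs=10, seed=1)
        a = pg.target_cross_validate(ds, folds=4, config=cfg, seed=5)
        b = pg.target_cross_validate(ds, folds=4, config=cfg, seed=5)
        assert a.mean.as_dict() == b.mean.as_dict()

    def test_too_few_positives_rejected(self):
        rng = np.random.default_rng(0)
        ds = random_feature_dataset(rng, 3, 30, mask_size=2, w=1)
        with pytest.raises(ValueError, match="stratified folds"):
            pg.target_cross_validate(ds, folds=10)

    def test_strong_signal_recovered(self, signal_bundle):
        ds = pg.build_dataset(
            signal_bundle.proteins, signal_bundle.tables, signal_bundle.annotations, w=2
        )
        cleaned, _ = pg.escalate_k(ds, target_ratio=3.0)
        result = pg.target_cross_validate(
            cleaned, folds=5, config=pg.MLPConfig(epochs=100, seed=0), seed=0
        )
        assert result.mean.gmean >= 0.9
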