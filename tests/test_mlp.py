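import numpy as np
import pytest
from sklearn.base import clone

import phogly as pg
from phogly.mlp import MomentumMLPClassifier, hidden_size_rule_a


def separable_2d(rng, n=40, gap=4.0):
    X = np.vstack([
        rng.normal(-gap / 2, 1.0, size=(n // 2, 2)),
        rng.normal(+gap / 2, 1.0, size=(n // 2, 2)),
    ])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestHiddenSizeRule:
    @pytest.mark.parametrize("n_features,expected", [(40, 21), (25, 13), (2, 2)])
    def test_rule_a(self, n_features, expected):
        assert hidden_size_rule_a(n_features) == expected

    def test_resolved_at_fit_time(self):
        rng = np.random.default_rng(0)
        X, y = separable_2d(rng)
        model = MomentumMLPClassifier(epochs=5).fit(X, y)
        assert model.hidden_size_ == 2


class TestTraining:
    def test_xor_learnable(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        model = MomentumMLPClassifier(hidden=4, epochs=3000, random_state=1).fit(X, y)
        assert np.array_equal(model.predict(X), y)

    def test_deterministic_weights_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        X, y = separable_2d(rng)
        a = MomentumMLPClassifier(epochs=50, random_state=7).fit(X, y)
        b = MomentumMLPClassifier(epochs=50, random_state=7).fit(X, y)
        np.testing.assert_array_equal(a.W1_, b.W1_)
        np.testing.assert_array_equal(a.w2_, b.w2_)
        assert a.b2_ == b.b2_

    def test_seed_changes_weights(self):
        rng = np.random.default_rng(1)
        X, y = separable_2d(rng)
        a = MomentumMLPClassifier(epochs=50, random_state=7).fit(X, y)
        b = MomentumMLPClassifier(epochs=50, random_state=8).fit(X, y)
        assert not np.array_equal(a.W1_, b.W1_)

    def test_separable_accuracy_over_seeds(self):
        """Training accuracy >= 0.95 on linearly separable data, 9+/10 seeds."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, y = separable_2d(rng)
            model = MomentumMLPClassifier(epochs=500, random_state=seed).fit(X, y)
            wins += np.mean(model.predict(X) == y) >= 0.95
        assert wins >= 9

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="both classes"):
            MomentumMLPClassifier(epochs=1).fit(X, np.ones(5))

    def test_nan_features_rejected(self):
        X = np.full((4, 2), np.nan)
        with pytest.raises(ValueError):
            MomentumMLPClassifier(epochs=1).fit(X, np.array([0, 1, 0, 1]))

    @pytest.mark.parametrize(
        "params", [{"learning_rate": -1}, {"momentum": 1.0}, {"epochs": 0},
                   {"hidden": 0}, {"threshold": 1.5}],
    )
    def test_invalid_hyperparameters(self, params):
        X = np.array([[0.0, 0], [1, 1]])
        with pytest.raises(ValueError):
            MomentumMLPClassifier(**params).fit(X, np.array([0, 1]))


class TestScalerHygiene:
    def test_scaler_fitted_on_training_split_only(self):
        rng = np.random.default_rng(2)
        X, y = separable_2d(rng)
        model = MomentumMLPClassifier(epochs=20, random_state=0).fit(X, y)
        np.testing.assert_array_equal(model.feature_min_, X.min(axis=0))
        np.testing.assert_array_equal(model.feature_max_, X.max(axis=0))
        # scaled training data spans exactly [-1, 1]
        Xs = model._scale(X)
        np.testing.assert_allclose(Xs.min(axis=0), -1.0)
        np.testing.assert_allclose(Xs.max(axis=0), 1.0)

    def test_validation_data_cannot_influence_weights(self):
        rng = np.random.default_rng(3)
        X, y = separable_2d(rng)
        Xval = rng.normal(size=(30, 2))
        a = MomentumMLPClassifier(epochs=20, random_state=0).fit(X, y)
        _ = a.decision_function(Xval)
        b = MomentumMLPClassifier(epochs=20, random_state=0).fit(X, y)
        _ = b.decision_function(rng.permutation(Xval))
        np.testing.assert_array_equal(a.W1_, b.W1_)
        np.testing.assert_array_equal(a.w2_, b.w2_)

    def test_constant_feature_maps_to_zero(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 0.5], [1.0, 0.9]])
        y = np.array([0, 1, 0, 1])
        model = MomentumMLPClassifier(epochs=5, random_state=0).fit(X, y)
        assert np.all(model._scale(X)[:, 0] == 0.0)


class TestPrediction:
    def test_scores_in_unit_interval(self, signal_bundle):
        ds = pg.build_dataset(
            signal_bundle.proteins, signal_bundle.tables, signal_bundle.annotations, w=2
        )
        model = pg.train_mlp(ds, pg.MLPConfig(epochs=20, seed=0))
        scores = pg.predict_scores(model, ds)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_duplicated_instance_same_score(self):
        rng = np.random.default_rng(4)
        X, y = separable_2d(rng)
        model = MomentumMLPClassifier(epochs=20, random_state=0).fit(X, y)
        s = model.decision_function(np.vstack([X[0], X[0]]))
        assert s[0] == s[1]

    def test_signal_recovery_score_separation(self, signal_bundle):
        ds = pg.build_dataset(
            signal_bundle.proteins, signal_bundle.tables, signal_bundle.annotations, w=2
        )
        model = pg.train_mlp(ds, pg.MLPConfig(epochs=100, seed=0))
        scores = pg.predict_scores(model, ds)
        assert scores[ds.y == 1].mean() > scores[ds.y == 0].mean()

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        X, y = separable_2d(rng)
        model = MomentumMLPClassifier(epochs=5, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            model.decision_function(np.zeros((3, 5)))

    def test_classify_threshold_and_ties(self):
        labels = pg.classify(np.array([0.7, 0.5, 0.49]), threshold=0.5)
        np.testing.assert_array_equal(labels, [1, 1, 0])

    def test_classify_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pg.classify(np.array([1.2]))
        with pytest.raises(ValueError):
            pg.classify(np.array([0.5]), threshold=1.1)


class TestEstimatorContract:
    def test_get_set_params_and_clone(self):
        model = MomentumMLPClassifier(hidden=7, epochs=10)
        params = model.get_params()
        assert params["hidden"] == 7 and params["momentum"] == 0.2
        fresh = clone(model)
        assert fresh.get_params() == params
        model.set_params(learning_rate=0.1)
        assert model.learning_rate == 0.1

    def test_predict_proba_columns(self):
        rng = np.random.default_rng(6)
        X, y = separable_2d(rng)
        model = MomentumMLPClassifier(epochs=20, random_state=0).fit(X, y)
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        np.testing.assert_array_equal(model.classes_, [0, 1])

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        X, y = separable_2d(rng)
        model = MomentumMLPClassifier(epochs=20, random_state=0).fit(X, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = MomentumMLPClassifier.from_json(path)
        np.testing.assert_array_equal(back.W1_, model.W1_)
        np.testing.assert_allclose(
            back.decision_function(X), model.decision_function(X)
        )
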