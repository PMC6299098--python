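"""Single-hidden-layer perceptron trained by momentum SGD.

This mirrors the classic Weka-style multilayer perceptron configuration used
for the lysine-site classifier: one hidden layer of logistic-sigmoid units,
hidden size ``'a' = floor((n_attributes + n_classes) / 2)``, learning rate
0.3 and momentum 0.2, with per-feature min-max scaling of the inputs to
``[-1, 1]`` fitted on the training split only.  Divergences from the Weka
layout are deliberate and documented: a single sigmoid output unit (the
positive-class probability) replaces the two-output layer — an equivalent
decision surface for two classes — and the loss is binary cross-entropy.

Training is plain stochastic gradient descent: one weight update per sample,
sample order reshuffled every epoch from the seeded generator, update rule
``v <- momentum * v - lr * grad; w <- w + v``.  For a fixed seed, data and
sample order the fitted weights are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import FeatureDataset

N_CLASSES = 2  # binary task; enters the hidden-size rule 'a'


def hidden_size_rule_a(n_features: int) -> int:
    """Weka's rule ``'a'``: ``floor((n_attributes + n_classes) / 2)``."""
    return max(1, (n_features + N_CLASSES) // 2)


@njit(cache=True)
def _sigmoid(z):
    if z > 60.0:
        return 1.0
    if z < -60.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def _sgd_train(X, y, perms, W1, b1, w2, b2, lr, momentum):
    """Per-sample momentum SGD on sigmoid-MLP cross-entropy (in-place)."""
    n, d = X.shape
    h = W1.shape[0]
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2)
    vb2 = 0.0
    hid = np.empty(h)
    for epoch in range(perms.shape[0]):
        for t in range(n):
            i = perms[epoch, t]
            x = X[i]
            # forward
            for j in range(h):
                z = b1[j]
                for f in range(d):
                    z += W1[j, f] * x[f]
                hid[j] = _sigmoid(z)
            z2 = b2
            for j in range(h):
                z2 += w2[j] * hid[j]
            p = _sigmoid(z2)
            # backward (cross-entropy + sigmoid output => delta = p - y)
            d2 = p - y[i]
            for j in range(h):
                d1 = d2 * w2[j] * hid[j] * (1.0 - hid[j])
                vw2[j] = momentum * vw2[j] - lr * d2 * hid[j]
                w2[j] += vw2[j]
                for f in range(d):
                    vW1[j, f] = momentum * vW1[j, f] - lr * d1 * x[f]
                    W1[j, f] += vW1[j, f]
                vb1[j] = momentum * vb1[j] - lr * d1
                b1[j] += vb1[j]
            vb2 = momentum * vb2 - lr * d2
            b2 += vb2
    return b2


class MomentumMLPClassifier(BaseEstimator, ClassifierMixin):
    """Binary MLP with one sigmoid hidden layer and momentum SGD.

    Parameters
    ----------
    hidden : int or "a"
        Hidden-layer size; ``"a"`` applies the rule
        ``floor((n_features + 2) / 2)`` at fit time.
    learning_rate : float
        SGD step size (default 0.3).
    momentum : float
        Momentum coefficient in ``[0, 1)`` (default 0.2).
    epochs : int
        Full passes over the training data (default 500).
    random_state : int
        Seeds weight initialisation and the per-epoch sample shuffles.
    threshold : float
        Decision threshold on the positive-class score; ties go to the
        positive class (``score >= threshold``).

    Attributes
    ----------
    W1_, b1_, w2_, b2_ : fitted weights.
    feature_min_, feature_max_ : per-feature min-max bounds fitted on the
        training split; inputs are mapped affinely to ``[-1, 1]`` (test
        values may land outside that interval and are not clipped).
    hidden_size_ : resolved hidden-layer width.
    """

    def __init__(
        self,
        hidden: int | str = "a",
        learning_rate: float = 0.3,
        momentum: float = 0.2,
        epochs: int = 500,
        random_state: int = 0,
        threshold: float = 0.5,
    ):
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.random_state = random_state
        self.threshold = threshold

    # -- internals -----------------------------------------------------
    def _check_params(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.hidden != "a" and (not isinstance(self.hidden, (int, np.integer)) or self.hidden < 1):
            raise ValueError("hidden must be 'a' or a positive integer")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = self.feature_max_ - self.feature_min_
        safe = np.where(span > 0, span, 1.0)
        scaled = 2.0 * (X - self.feature_min_) / safe - 1.0
        return np.where(span > 0, scaled, 0.0)

    # -- estimator API -------------------------------------------------
    def fit(self, X, y) -> "MomentumMLPClassifier":
        self._check_params()
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if not set(classes) <= {0, 1} or len(classes) < 2:
            raise ValueError("training data must contain both classes 0 and 1")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]

        self.feature_min_ = X.min(axis=0)
        self.feature_max_ = X.max(axis=0)
        Xs = self._scale(X)

        h = hidden_size_rule_a(X.shape[1]) if self.hidden == "a" else int(self.hidden)
        self.hidden_size_ = h

        rng = np.random.default_rng(self.random_state)
        W1 = rng.uniform(-0.5, 0.5, size=(h, X.shape[1]))
        b1 = rng.uniform(-0.5, 0.5, size=h)
        w2 = rng.uniform(-0.5, 0.5, size=h)
        b2 = float(rng.uniform(-0.5, 0.5))
        perms = np.empty((self.epochs, X.shape[0]), dtype=np.int64)
        for e in range(self.epochs):
            perms[e] = rng.permutation(X.shape[0])

        b2 = _sgd_train(
            np.ascontiguousarray(Xs),
            y.astype(np.float64),
            perms,
            W1, b1, w2, b2,
            float(self.learning_rate),
            float(self.momentum),
        )
        self.W1_, self.b1_, self.w2_, self.b2_ = W1, b1, w2, float(b2)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Positive-class probability in ``[0, 1]`` (sigmoid output)."""
        check_is_fitted(self, "W1_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.n_features_in_}"
            )
        Xs = self._scale(X)
        hid = 1.0 / (1.0 + np.exp(-np.clip(Xs @ self.W1_.T + self.b1_, -60, 60)))
        z2 = np.clip(hid @ self.w2_ + self.b2_, -60, 60)
        return 1.0 / (1.0 + np.exp(-z2))

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return classify(self.decision_function(X), self.threshold)

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        check_is_fitted(self, "W1_")
        payload = {
            "config": self.get_params(),
            "hidden_size": self.hidden_size_,
            "feature_min": self.feature_min_.tolist(),
            "feature_max": self.feature_max_.tolist(),
            "W1": self.W1_.tolist(),
            "b1": self.b1_.tolist(),
            "w2": self.w2_.tolist(),
            "b2": self.b2_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MomentumMLPClassifier":
        payload = json.loads(Path(path).read_text())
        model = cls(**payload["config"])
        model.hidden_size_ = payload["hidden_size"]
        model.feature_min_ = np.array(payload["feature_min"])
        model.feature_max_ = np.array(payload["feature_max"])
        model.W1_ = np.array(payload["W1"])
        model.b1_ = np.array(payload["b1"])
        model.w2_ = np.array(payload["w2"])
        model.b2_ = float(payload["b2"])
        model.n_features_in_ = model.W1_.shape[1]
        model.classes_ = np.array([0, 1])
        return model


@dataclass
class MLPConfig:
    """Hyperparameter bundle for the site classifier."""

    hidden: int | str = "a"
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 500
    seed: int = 0
    threshold: float = 0.5

    def make_estimator(self) -> MomentumMLPClassifier:
        return MomentumMLPClassifier(
            hidden=self.hidden,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            epochs=self.epochs,
            random_state=self.seed,
            threshold=self.threshold,
        )


def train_mlp(train: FeatureDataset, config: MLPConfig | None = None) -> MomentumMLPClassifier:
    """Fit the classifier on a feature dataset (scaler fitted here only)."""
    config = config or MLPConfig()
    return config.make_estimator().fit(train.X, train.y)


def predict_scores(model: MomentumMLPClassifier, dataset: FeatureDataset) -> np.ndarray:
    """Positive-class scores in ``[0, 1]``, one per instance."""
    return model.decision_function(dataset.X)


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold scores into labels; ties (score == threshold) go positive."""
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return (scores >= threshold).astype(int)
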