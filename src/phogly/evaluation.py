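"""Performance metrics and the target cross-validation protocol.

Seven statistics describe a binary site predictor here: sensitivity
``TP/(TP+FN)``, specificity ``TN/(TN+FP)``, their geometric mean (G-Mean —
the selection criterion throughout this package, since a predictor can score
high accuracy on imbalanced data while missing every modified lysine),
accuracy, Matthews correlation coefficient, F-Measure
``2TP/(2TP+FP+FN)`` and the area under the ROC curve.  AUC is computed from
continuous classifier scores as the tie-aware normalised Mann–Whitney
statistic: the probability that a random positive outscores a random
negative, ties counting one half.

Whenever a metric's denominator is zero the metric is defined as 0
(sensitivity/specificity/F-Measure with an empty class, MCC with any zero
factor under the root).

The cross-validation is the "target" variant required whenever the training
data are rebalanced: folds are assigned on the dataset BEFORE any cleaning,
each training split is then rebalanced (KNN cleaning to a 2:1
negative:positive ratio by default) while its validation fold is scored in
its original, untouched form, so every annotated site is evaluated exactly
once.  Fold assignment is stratified and seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .features import FeatureDataset
from .imbalance import CleaningReport, rebalance_training
from .mlp import MLPConfig, classify

METRIC_NAMES = (
    "sensitivity", "specificity", "gmean", "accuracy", "mcc", "fmeasure", "auc",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    gmean: float
    accuracy: float
    mcc: float
    fmeasure: float
    auc: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Standard 2x2 table of binary labels vs binary predictions."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Evaluate the six threshold metrics from a confusion table.

    AUC needs continuous scores and is left NaN here; see :func:`roc_auc`.
    """
    if c.n == 0:
        raise ValueError("empty confusion table")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    gmean = math.sqrt(sens * spec)
    acc = (c.tn + c.tp) / c.n
    mcc_den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = (c.tn * c.tp - c.fn * c.fp) / math.sqrt(mcc_den) if mcc_den > 0 else 0.0
    fmeas = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    return MetricSet(
        sensitivity=sens, specificity=spec, gmean=gmean,
        accuracy=acc, mcc=mcc, fmeasure=fmeas,
    )


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Tie-aware AUC via the normalised Mann–Whitney rank statistic.

    Equals the probability that a uniformly random positive receives a
    higher score than a uniformly random negative, ties counted 1/2 —
    equivalently the trapezoidal area under the empirical ROC curve.
    Invariant under strictly increasing transforms of the scores.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 wins
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def score_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricSet:
    """All seven metrics from continuous scores at a decision threshold."""
    m = compute_metrics(confusion(labels, classify(scores, threshold)))
    m.auc = roc_auc(labels, scores)
    return m


@dataclass
class FoldRecord:
    """One CV iteration: validation rows, metrics, cleaning audit."""

    fold: int
    val_indices: np.ndarray
    metrics: MetricSet
    cleaning: CleaningReport
    train_pos_before: int
    train_pos_after: int


@dataclass
class CVResult:
    folds: list[FoldRecord]
    mean: MetricSet
    seed: int

    @property
    def fold_metrics(self) -> list[MetricSet]:
        return [f.metrics for f in self.folds]

    def to_rows(self) -> list[dict]:
        rows = []
        for f in self.folds:
            row = {"fold": f.fold}
            row.update(f.metrics.as_dict())
            rows.append(row)
        mean_row = {"fold": "mean"}
        mean_row.update(self.mean.as_dict())
        rows.append(mean_row)
        return rows


def _mean_metrics(per_fold: list[MetricSet]) -> MetricSet:
    values = {
        name: float(np.mean([getattr(m, name) for m in per_fold]))
        for name in METRIC_NAMES
    }
    return MetricSet(**values)


def target_cross_validate(
    dataset: FeatureDataset,
    folds: int = 10,
    rebalance_ratio: float = 2.0,
    config: MLPConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """Target k-fold cross-validation with per-fold training rebalancing.

    Folds are assigned (stratified, seeded shuffle) on the dataset before
    any cleaning.  Per iteration the nine training folds are rebalanced to
    ``rebalance_ratio`` negatives per positive with the KNN cleaning
    treatment, the MLP is trained on the cleaned split, and the untouched
    validation fold is scored.  Per-fold metric sets and their arithmetic
    means are returned; fold macro-averaging follows the protocol's
    "compute the average of each metric".

    The per-fold record keeps the validation row indices and the training
    positive counts before/after cleaning so leakage and positive
    conservation can be audited.
    """
    config = config or MLPConfig()
    if dataset.n_pos < folds or dataset.n_neg < folds:
        raise ValueError(
            f"need at least {folds} samples of each class for {folds} "
            f"stratified folds (have {dataset.n_pos} pos / {dataset.n_neg} neg)"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    records: list[FoldRecord] = []
    for fold_no, (train_idx, val_idx) in enumerate(
        splitter.split(dataset.X, dataset.y)
    ):
        train = dataset.subset(train_idx)
        val = dataset.subset(val_idx)
        if val.n_pos == 0 or val.n_neg == 0:
            raise RuntimeError(f"fold {fold_no}: validation split lost a class")
        pos_before = train.n_pos
        cleaned, report = rebalance_training(train, target_ratio=rebalance_ratio)
        fold_cfg = MLPConfig(
            hidden=config.hidden, learning_rate=config.learning_rate,
            momentum=config.momentum, epochs=config.epochs,
            seed=config.seed + fold_no, threshold=config.threshold,
        )
        model = fold_cfg.make_estimator().fit(cleaned.X, cleaned.y)
        scores = model.decision_function(val.X)
        metrics = score_metrics(val.y, scores, threshold=config.threshold)
        records.append(
            FoldRecord(
                fold=fold_no, val_indices=np.asarray(val_idx),
                metrics=metrics, cleaning=report,
                train_pos_before=pos_before, train_pos_after=cleaned.n_pos,
            )
        )
    mean = _mean_metrics([r.metrics for r in records])
    result = CVResult(folds=records, mean=mean, seed=seed)
    _audit_partition(result, len(dataset))
    return result


def _audit_partition(result: CVResult, n: int) -> None:
    """Every instance in exactly one validation fold; positives conserved."""
    all_val = np.concatenate([f.val_indices for f in result.folds])
    if len(all_val) != n or len(np.unique(all_val)) != n:
        raise RuntimeError("validation folds do not partition the dataset")
    for f in result.folds:
        if f.train_pos_after != f.train_pos_before:
            raise RuntimeError(
                f"fold {f.fold}: cleaning changed the training positive count"
            )
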