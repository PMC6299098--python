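"""K-nearest-neighbour cleaning treatment for class imbalance.

Annotated lysine datasets are heavily skewed toward non-modified sites (the
motivating regime is roughly 29 negatives per positive).  The cleaning
treatment computes Euclidean distances between every pair of samples on the
raw feature vectors and removes each negative whose ``k`` nearest
neighbours (over all samples, self excluded) include at least one positive;
positives are never removed.  ``k`` starts at ``floor(n_neg / n_pos)`` and
is escalated by 1 — each value re-applied to the ORIGINAL dataset, not
cumulatively — until the surviving negative:positive ratio drops to the
target (3:1 for benchmark construction, 2:1 for per-fold training
rebalancing inside cross-validation).

Neighbour ties at equal distance are broken by ascending instance index so
that cleaning is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import pairwise_distances as _sk_pairwise

from .features import FeatureDataset


@dataclass
class CleaningReport:
    """Record of one escalated cleaning run.

    ``partial`` marks the degenerate fallback in training rebalancing where
    a single k step would have removed every negative (see
    :func:`rebalance_training`).
    """

    k_initial: int
    k_final: int
    removed_ids: list[tuple[str, int]]
    n_neg_before: int
    n_neg_after: int
    n_pos: int
    target_ratio: float
    partial: bool = False

    def to_dict(self) -> dict:
        return {
            "k_initial": self.k_initial,
            "k_final": self.k_final,
            "n_removed": len(self.removed_ids),
            "removed_ids": [f"{pid}:{pos + 1}" for pid, pos in self.removed_ids],
            "n_neg_before": self.n_neg_before,
            "n_neg_after": self.n_neg_after,
            "n_pos": self.n_pos,
            "target_ratio": self.target_ratio,
            "partial": self.partial,
        }


def pairwise_distance_table(dataset: FeatureDataset) -> np.ndarray:
    """Symmetric Euclidean distance matrix over the raw feature vectors."""
    if not np.all(np.isfinite(dataset.X)):
        raise ValueError("feature matrix contains non-finite values")
    d = _sk_pairwise(dataset.X, metric="euclidean")
    np.fill_diagonal(d, 0.0)
    return d


def _first_positive_rank(dataset: FeatureDataset) -> np.ndarray:
    """For each sample, the neighbour rank (1-based) of its nearest positive.

    Neighbours are all other samples ordered by Euclidean distance, ties
    broken by ascending index.  A sample whose neighbour list contains no
    positive (only possible when it is the sole positive itself) gets rank
    ``n`` (unreachable by any valid ``k <= n - 1``).
    """
    n = len(dataset)
    d = pairwise_distance_table(dataset)
    np.fill_diagonal(d, np.inf)  # self excluded from the neighbour pool
    order = np.argsort(d, axis=1, kind="stable")  # stable => index tie-break
    is_pos = dataset.y == 1
    pos_in_order = is_pos[order]  # (n, n): neighbour ranks holding positives
    any_pos = pos_in_order.any(axis=1)
    first = np.where(any_pos, pos_in_order.argmax(axis=1) + 1, n)
    return first


def knn_clean_at_k(
    dataset: FeatureDataset, k: int
) -> tuple[FeatureDataset, list[tuple[str, int]]]:
    """Single batch cleaning pass at a fixed ``k``.

    Neighbourhoods are computed on the full input dataset; every negative
    whose ``k`` nearest neighbours include a positive is removed.  Returns
    the cleaned dataset and the ids of the removed negatives.
    """
    n = len(dataset)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the dataset size {n}")
    if dataset.n_pos == 0 or dataset.n_neg == 0:
        raise ValueError("cleaning requires at least one sample of each class")
    first = _first_positive_rank(dataset)
    remove = (dataset.y == 0) & (first <= k)
    cleaned = dataset.subset(~remove)
    removed_ids = [dataset.ids[i] for i in np.flatnonzero(remove)]
    return cleaned, removed_ids


def escalate_k(
    dataset: FeatureDataset,
    target_ratio: float = 3.0,
    k_start: int | None = None,
) -> tuple[FeatureDataset, CleaningReport]:
    """Escalate ``k`` until the cleaned negative:positive ratio <= target.

    ``k_start`` defaults to ``floor(n_neg / n_pos)``.  Each candidate ``k``
    is a fresh pass over the original dataset; because neighbour sets are
    nested in ``k`` the removed set only grows, so the smallest satisfying
    ``k`` is found by scanning the per-negative first-positive ranks once.
    A dataset already at or below the target ratio is returned unchanged
    with ``k_final = k_start``.
    """
    if target_ratio < 1:
        raise ValueError("target_ratio must be >= 1")
    n = len(dataset)
    n_pos, n_neg = dataset.n_pos, dataset.n_neg
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cleaning requires at least one sample of each class")
    if k_start is None:
        k_start = max(1, n_neg // n_pos)
    if k_start < 1:
        raise ValueError("k_start must be >= 1")

    if n_neg / n_pos <= target_ratio:
        report = CleaningReport(
            k_initial=k_start, k_final=k_start, removed_ids=[],
            n_neg_before=n_neg, n_neg_after=n_neg, n_pos=n_pos,
            target_ratio=target_ratio,
        )
        return dataset, report

    first = _first_positive_rank(dataset)
    neg_first = first[dataset.y == 0]
    for k in range(k_start, n):
        surviving = int(np.sum(neg_first > k))
        if surviving / n_pos <= target_ratio:
            cleaned, removed_ids = knn_clean_at_k(dataset, k)
            report = CleaningReport(
                k_initial=k_start, k_final=k, removed_ids=removed_ids,
                n_neg_before=n_neg, n_neg_after=cleaned.n_neg, n_pos=n_pos,
                target_ratio=target_ratio,
            )
            assert cleaned.n_pos == n_pos
            return cleaned, report
    raise RuntimeError(
        f"target ratio {target_ratio} unreachable: even at k={n - 1} the "
        f"surviving negatives ({int(np.sum(neg_first > n - 1))}) exceed "
        f"{target_ratio} x {n_pos} positives"
    )


def rebalance_training(
    train_split: FeatureDataset, target_ratio: float = 2.0
) -> tuple[FeatureDataset, CleaningReport]:
    """Rebalance a training split only (per-fold use inside CV).

    Identical to :func:`escalate_k` except in one degenerate regime: when
    the classes are so well separated that every negative's nearest positive
    sits at (nearly) the same neighbour rank, a single k step can jump from
    removing nothing to removing every negative, leaving nothing to train
    on.  In that case the removal is truncated at the final k: negatives are
    removed in ascending order of their first-positive neighbour rank (ties
    by index) only until the ratio target holds, so the training split keeps
    ``floor(target_ratio * n_pos)`` negatives — the ones farthest from the
    positives.  The report flags this with ``partial=True``.  Positives are
    never touched either way.
    """
    cleaned, report = escalate_k(train_split, target_ratio=target_ratio)
    if cleaned.n_neg > 0:
        return cleaned, report
    first = _first_positive_rank(train_split)
    neg_rows = np.flatnonzero(train_split.y == 0)
    order = neg_rows[np.lexsort((neg_rows, first[neg_rows]))]
    n_keep = int(target_ratio * train_split.n_pos)
    if n_keep < 1:
        raise RuntimeError("target ratio leaves no negatives to train on")
    remove_rows = set(order[: len(neg_rows) - n_keep].tolist())
    keep = np.array([i for i in range(len(train_split)) if i not in remove_rows])
    partial = train_split.subset(keep)
    report = CleaningReport(
        k_initial=report.k_initial, k_final=report.k_final,
        removed_ids=[train_split.ids[i] for i in sorted(remove_rows)],
        n_neg_before=train_split.n_neg, n_neg_after=partial.n_neg,
        n_pos=train_split.n_pos, target_ratio=target_ratio, partial=True,
    )
    return partial, report


def initial_k(n_neg: int, n_pos: int) -> int:
    """The escalation starting point: ``floor(n_neg / n_pos)``."""
    if n_pos <= 0:
        raise ValueError("n_pos must be positive")
    return max(1, n_neg // n_pos)


class KNNCleaner:
    """Resampler facade over :func:`escalate_k` (``fit_resample`` idiom).

    Parameters
    ----------
    target_ratio : float
        Largest acceptable negative:positive ratio after cleaning.
    k_start : int or None
        Starting neighbourhood size; ``None`` uses ``floor(n_neg / n_pos)``.
    """

    def __init__(self, target_ratio: float = 3.0, k_start: int | None = None):
        self.target_ratio = target_ratio
        self.k_start = k_start

    def get_params(self, deep: bool = True) -> dict:
        return {"target_ratio": self.target_ratio, "k_start": self.k_start}

    def set_params(self, **params) -> "KNNCleaner":
        for key, value in params.items():
            if key not in ("target_ratio", "k_start"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit_resample(self, dataset: FeatureDataset) -> FeatureDataset:
        cleaned, report = escalate_k(
            dataset, target_ratio=self.target_ratio, k_start=self.k_start
        )
        self.report_ = report
        return cleaned
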