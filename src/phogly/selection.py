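"""Wrapper feature selection over whole property groups.

Backward elimination ranks the eight structural property tracks by greedily
removing, at each level, the property whose removal yields the highest mean
cross-validated G-Mean; the survivor of each level progresses, so each
elimination shrinks the feature vector by one window's worth of slots
(``2w + 1`` features, 5 at the default half-width).  The procedure runs
until a single property remains, producing a full ranking (eliminated last
= most important) and the best-scoring mask seen anywhere along the way.

Candidate removals within a level are compared on identical CV fold
assignments (same seed, same rows), so the comparison reflects the feature
change rather than split noise.  Ties in candidate G-Mean are broken by
removing the property latest in canonical track order.

A companion scan evaluates the full pipeline (extraction, cleaning to a 3:1
negative:positive ratio, target CV) across window half-widths to pick the
segment size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .features import (
    FULL_MASK,
    FeatureDataset,
    apply_property_mask,
    build_dataset,
    canonical_mask,
)
from .imbalance import escalate_k
from .io import PROPERTIES, ProteinRecord, ResiduePropertyTable, SiteAnnotation
from .mlp import MLPConfig
from .evaluation import CVResult, target_cross_validate


@dataclass
class EliminationLevel:
    """One committed elimination: all candidates tried, one removed."""

    level: int
    candidates: list[tuple[str, float]]  # (property removed, mean G-Mean)
    eliminated: str
    surviving_mask: tuple[str, ...]
    gmean: float  # mean G-Mean of the committed (surviving) mask


@dataclass
class EliminationTrace:
    baseline_gmean: float  # full-mask CV before any elimination
    levels: list[EliminationLevel]
    ranking: tuple[str, ...]  # most important first
    best_mask: tuple[str, ...]
    best_gmean: float

    def to_rows(self) -> list[dict]:
        rows = [
            {"level": 0, "candidate": "(none)", "removed": "",
             "gmean": self.baseline_gmean, "committed": True}
        ]
        for lvl in self.levels:
            for prop, g in lvl.candidates:
                rows.append(
                    {"level": lvl.level, "candidate": prop, "removed": lvl.eliminated,
                     "gmean": g, "committed": prop == lvl.eliminated}
                )
        return rows


def _mean_gmean(result: CVResult) -> float:
    return result.mean.gmean


def backward_eliminate(
    dataset: FeatureDataset,
    folds: int = 10,
    rebalance_ratio: float = 2.0,
    config: MLPConfig | None = None,
    seed: int = 0,
) -> EliminationTrace:
    """Greedy backward elimination over property groups.

    The dataset must carry the full 8-track mask.  At a level with ``m``
    surviving properties all ``m`` single-property removals are evaluated by
    :func:`~phogly.evaluation.target_cross_validate`; the removal with the
    highest mean G-Mean is committed.  The trace records every candidate
    evaluation, the committed path, the final importance ranking and the
    best mask over all levels (the full mask included).
    """
    if dataset.mask != FULL_MASK:
        raise ValueError("backward elimination starts from the full 8-property mask")
    config = config or MLPConfig()

    def evaluate(mask: tuple[str, ...]) -> float:
        sub = apply_property_mask(dataset, mask)
        return _mean_gmean(
            target_cross_validate(
                sub, folds=folds, rebalance_ratio=rebalance_ratio,
                config=config, seed=seed,
            )
        )

    baseline = evaluate(FULL_MASK)
    best_mask, best_gmean = FULL_MASK, baseline

    current = list(FULL_MASK)
    levels: list[EliminationLevel] = []
    eliminated_order: list[str] = []
    level_no = 1
    while len(current) > 1:
        candidates: list[tuple[str, float]] = []
        chosen, chosen_g = None, -1.0
        for prop in current:  # canonical order; >= keeps the latest on ties
            trial = tuple(p for p in current if p != prop)
            g = evaluate(trial)
            candidates.append((prop, g))
            if g >= chosen_g:
                chosen, chosen_g = prop, g
        assert chosen is not None
        current = [p for p in current if p != chosen]
        surviving = canonical_mask(current)
        levels.append(
            EliminationLevel(
                level=level_no, candidates=candidates, eliminated=chosen,
                surviving_mask=surviving, gmean=chosen_g,
            )
        )
        eliminated_order.append(chosen)
        if chosen_g > best_gmean:
            best_mask, best_gmean = surviving, chosen_g
        level_no += 1

    ranking = tuple(current) + tuple(reversed(eliminated_order))
    assert sorted(ranking) == sorted(PROPERTIES)
    return EliminationTrace(
        baseline_gmean=baseline, levels=levels, ranking=ranking,
        best_mask=best_mask, best_gmean=best_gmean,
    )


@dataclass
class WindowScanRow:
    w: int
    n_features: int
    gmean: float | None
    error: str | None = None


def scan_window_sizes(
    proteins: Sequence[ProteinRecord],
    tables: Mapping[str, ResiduePropertyTable],
    annotations: Sequence[SiteAnnotation],
    w_values: Sequence[int],
    mask: Sequence[str] = FULL_MASK,
    clean_ratio: float = 3.0,
    folds: int = 10,
    rebalance_ratio: float = 2.0,
    config: MLPConfig | None = None,
    seed: int = 0,
) -> list[WindowScanRow]:
    """Mean CV G-Mean of the full pipeline per window half-width.

    For each ``w`` (half-widths 1..15 are supported): extract features,
    clean the negatives to ``clean_ratio`` per positive, run target CV.
    A failure at one ``w`` is recorded in its row and the scan continues.
    """
    mask = canonical_mask(mask)
    if not set(w_values) <= set(range(1, 16)):
        raise ValueError("window half-widths must lie in 1..15")
    rows: list[WindowScanRow] = []
    for w in w_values:
        n_feat = (2 * w + 1) * len(mask)
        try:
            ds = build_dataset(proteins, tables, annotations, w=w, mask=mask)
            cleaned, _ = escalate_k(ds, target_ratio=clean_ratio)
            result = target_cross_validate(
                cleaned, folds=folds, rebalance_ratio=rebalance_ratio,
                config=config, seed=seed,
            )
            rows.append(WindowScanRow(w=w, n_features=n_feat, gmean=result.mean.gmean))
        except Exception as exc:  # per-w failures recorded, scan continues
            rows.append(WindowScanRow(w=w, n_features=n_feat, gmean=None, error=str(exc)))
    return rows
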