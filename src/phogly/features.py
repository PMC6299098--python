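"""Peptide-window feature extraction around annotated lysine residues.

Each lysine site is described by the residues at offsets ``-w .. +w`` around
it (default half-width ``w = 2``, i.e. a 5-residue segment with the lysine at
the centre).  When the lysine sits closer than ``w`` residues to a sequence
terminus the missing slots are filled by the mirror effect: the slot at
offset ``-i`` borrows the residue at offset ``+i`` and vice versa, a
reflection across the central lysine.  The per-residue structural property
values of each window slot (mirrored slots copy their source residue's
values verbatim) are flattened slot-major — outer loop over offsets
``-w .. +w``, inner loop over the active properties in canonical order —
giving ``(2w + 1) x |mask|`` features per site (40 for the full 8-property
mask at ``w = 2``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import (
    PROPERTIES,
    ProteinRecord,
    ResiduePropertyTable,
    SiteAnnotation,
)

logger = logging.getLogger(__name__)

REAL = "real"
MIRRORED = "mirrored"


class WindowError(ValueError):
    """Raised when no valid window exists for a site (sequence too short)."""


def canonical_mask(properties: Sequence[str]) -> tuple[str, ...]:
    """Validate a property subset and return it in canonical track order."""
    props = list(properties)
    if not props:
        raise ValueError("property mask must be non-empty")
    bad = set(props) - set(PROPERTIES)
    if bad:
        raise ValueError(f"unknown properties: {sorted(bad)}")
    if len(set(props)) != len(props):
        raise ValueError("property mask contains duplicates")
    return tuple(p for p in PROPERTIES if p in props)


FULL_MASK: tuple[str, ...] = canonical_mask(PROPERTIES)


@dataclass(frozen=True)
class PeptideWindow:
    """Resolved window around one lysine: ``2w + 1`` sequence indices.

    ``indices[w]`` is the lysine itself and always flagged ``real``; a slot
    flagged ``mirrored`` references the residue reflected across the centre.
    """

    w: int
    indices: tuple[int, ...]
    flags: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.indices) != 2 * self.w + 1 or len(self.flags) != 2 * self.w + 1:
            raise ValueError("window must have exactly 2w+1 slots")
        if self.flags[self.w] != REAL:
            raise ValueError("centre slot must be real")


def window_indices(sequence_length: int, position: int, w: int) -> PeptideWindow:
    """Map window offsets ``-w .. +w`` at ``position`` to sequence indices.

    Out-of-range offsets are mirrored across the centre (offset ``-i``
    borrows the index at ``+i`` and symmetrically).  If for some ``i`` both
    ``position - i`` and ``position + i`` fall outside the sequence no valid
    window exists and :class:`WindowError` is raised.
    """
    if w < 1:
        raise ValueError("half-width w must be >= 1")
    if not 0 <= position < sequence_length:
        raise ValueError(
            f"position {position} out of range for length {sequence_length}"
        )
    indices: list[int] = []
    flags: list[str] = []
    for off in range(-w, w + 1):
        idx = position + off
        if 0 <= idx < sequence_length:
            indices.append(idx)
            flags.append(REAL)
            continue
        mirror = position - off
        if 0 <= mirror < sequence_length:
            indices.append(mirror)
            flags.append(MIRRORED)
        else:
            raise WindowError(
                f"no residue at offset {off:+d} or its mirror {-off:+d} from "
                f"position {position} (sequence length {sequence_length})"
            )
    return PeptideWindow(w=w, indices=tuple(indices), flags=tuple(flags))


def window_peptide(sequence: str, window: PeptideWindow) -> str:
    """The (possibly mirror-padded) peptide string a window describes."""
    return "".join(sequence[i] for i in window.indices)


def build_site_vector(
    table: ResiduePropertyTable,
    window: PeptideWindow,
    mask: Sequence[str] = FULL_MASK,
) -> np.ndarray:
    """Flatten a window's property values into a feature vector.

    Slot-major order: for each offset ``-w .. +w`` in turn, the masked
    properties in canonical order.  Mirrored slots copy the source residue's
    values verbatim.  Length is ``(2w + 1) * |mask|``.
    """
    mask = canonical_mask(mask)
    if max(window.indices) >= table.length:
        raise ValueError(
            f"window index {max(window.indices)} out of range for table "
            f"{table.protein_id!r} (length {table.length})"
        )
    cols = [PROPERTIES.index(p) for p in mask]
    return table.values[np.array(window.indices)][:, cols].reshape(-1)


@dataclass(frozen=True)
class SiteInstance:
    """One labelled lysine site with its window and flattened features."""

    protein_id: str
    position: int  # 0-based
    label: int
    window: PeptideWindow
    features: np.ndarray


@dataclass
class FeatureDataset:
    """A labelled feature matrix over lysine sites.

    ``X`` is ``(n, (2w+1)*|mask|)``, ``y`` the binary labels and ``ids`` the
    ``(protein_id, 0-based position)`` pair for each row.  ``mask`` is always
    stored in canonical property order.
    """

    X: np.ndarray
    y: np.ndarray
    ids: list[tuple[str, int]]
    w: int
    mask: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.mask = canonical_mask(self.mask)
        n = self.X.shape[0]
        if self.y.shape != (n,) or len(self.ids) != n:
            raise ValueError("X, y and ids must agree in length")
        expected = (2 * self.w + 1) * len(self.mask)
        if self.X.shape[1] != expected:
            raise ValueError(
                f"feature length {self.X.shape[1]} != (2w+1)*|mask| = {expected}"
            )
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.y == 0))

    def subset(self, rows: np.ndarray) -> "FeatureDataset":
        """Row subset (boolean mask or index array); metadata shared."""
        rows = np.asarray(rows)
        idx = np.flatnonzero(rows) if rows.dtype == bool else rows
        return FeatureDataset(
            X=self.X[idx],
            y=self.y[idx],
            ids=[self.ids[i] for i in idx],
            w=self.w,
            mask=self.mask,
        )


@dataclass
class ExtractionReport:
    """Sites skipped during dataset construction, with reasons."""

    skipped: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def build_dataset(
    proteins: Sequence[ProteinRecord],
    tables: Mapping[str, ResiduePropertyTable],
    annotations: Sequence[SiteAnnotation],
    w: int = 2,
    mask: Sequence[str] = FULL_MASK,
    report: ExtractionReport | None = None,
) -> FeatureDataset:
    """Extract one feature row per valid annotation.

    Every annotation must reference a known protein with a matching property
    table.  Sites whose window cannot be built (protein shorter than the
    mirror rule can serve) are skipped with a warning and logged in
    ``report``; the batch never aborts on a per-site window failure.
    """
    mask = canonical_mask(mask)
    by_id = {p.id: p for p in proteins}
    rows: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[tuple[str, int]] = []
    for ann in annotations:
        if ann.protein_id not in by_id:
            raise ValueError(f"annotation references unknown protein {ann.protein_id!r}")
        if ann.protein_id not in tables:
            raise ValueError(f"no property table for protein {ann.protein_id!r}")
        protein = by_id[ann.protein_id]
        table = tables[ann.protein_id]
        table.check_against(protein)
        try:
            window = window_indices(len(protein), ann.position, w)
        except WindowError as exc:
            logger.warning("skipping site %s:%d: %s", ann.protein_id, ann.position + 1, exc)
            if report is not None:
                report.skipped.append((ann.protein_id, ann.position, str(exc)))
            continue
        rows.append(build_site_vector(table, window, mask))
        labels.append(ann.label)
        ids.append((ann.protein_id, ann.position))
    if not rows:
        raise ValueError("no extractable sites (all annotations skipped)")
    return FeatureDataset(
        X=np.vstack(rows), y=np.array(labels), ids=ids, w=w, mask=mask
    )


def apply_property_mask(
    dataset: FeatureDataset, mask: Sequence[str]
) -> FeatureDataset:
    """Restrict a dataset to a sub-mask of its properties.

    Drops every window slot of the removed properties, so removing one
    property shrinks the vector by ``2w + 1``.  Labels and ids are unchanged.
    """
    mask = canonical_mask(mask)
    if not set(mask) <= set(dataset.mask):
        raise ValueError(
            f"mask {mask} is not a subset of the dataset mask {dataset.mask}"
        )
    keep = [i for i, p in enumerate(dataset.mask) if p in mask]
    n_slots = 2 * dataset.w + 1
    cols = np.concatenate(
        [np.array(keep) + s * len(dataset.mask) for s in range(n_slots)]
    )
    return FeatureDataset(
        X=dataset.X[:, cols],
        y=dataset.y.copy(),
        ids=list(dataset.ids),
        w=dataset.w,
        mask=mask,
    )
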