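"""Readers and writers for the package's external formats.

Four formats are handled here:

* protein sequences in FASTA (via :mod:`Bio.SeqIO`);
* per-residue structural-property tables in two dialects — the package's
  native tab-separated layout and the whitespace layout emitted by
  sequence-based structure predictors (index, AA, SS letter, ASA, phi, psi,
  theta, tau, P(C), P(E), P(H));
* site-label annotations ``protein_id, position, label``;
* flat feature-dataset files: CSV with a ``#``-prefixed metadata header
  recording the window half-width, the active property mask and the column
  names, so the file is self-describing and diffable.

Positions are 1-based in every external file and converted to 0-based at
this module's boundary.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: Canonical order of the eight per-residue structural property tracks:
#: predicted accessible surface area, the three secondary-structure
#: probabilities (coil, strand, helix) and the four backbone angles.
PROPERTIES: tuple[str, ...] = ("asa", "pc", "pe", "ph", "phi", "psi", "theta", "tau")

#: The 20 canonical amino-acid letters.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

_PROBABILITY_TRACKS = ("pc", "pe", "ph")
_ANGLE_TRACKS = ("phi", "psi", "theta", "tau")


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 canonical amino-acid letters."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise FormatError(
                f"protein {self.id!r}: non-canonical residue(s) "
                f"{sorted(bad)}; structural tracks are undefined for them"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ResiduePropertyTable:
    """Per-residue 8-track structural profile for one protein.

    ``values`` is an ``(L, 8)`` float array with columns in the canonical
    :data:`PROPERTIES` order.  Invariants (checked in ``validate``): the
    residue letters match the sequence position-wise, the coil/strand/helix
    probabilities lie in [0, 1], the backbone angles in [-180, 180] degrees
    and ASA is non-negative.  Probabilities are stored as given — the row
    sum is recorded by :meth:`probability_row_sums` but never enforced.
    """

    protein_id: str
    residues: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    @property
    def length(self) -> int:
        return len(self.residues)

    def track(self, name: str) -> np.ndarray:
        return self.values[:, PROPERTIES.index(name)]

    def probability_row_sums(self) -> np.ndarray:
        return self.track("pc") + self.track("pe") + self.track("ph")

    def validate(self) -> None:
        if self.values.shape != (len(self.residues), len(PROPERTIES)):
            raise FormatError(
                f"property table {self.protein_id!r}: value block shape "
                f"{self.values.shape} does not match {len(self.residues)} "
                f"residues x {len(PROPERTIES)} tracks"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError(f"property table {self.protein_id!r}: non-finite values")
        for name in _PROBABILITY_TRACKS:
            t = self.track(name)
            if np.any((t < 0.0) | (t > 1.0)):
                row = int(np.argmax((t < 0.0) | (t > 1.0))) + 1
                raise FormatError(
                    f"property table {self.protein_id!r}, row {row}: "
                    f"{name}={t[row - 1]!r} outside [0, 1]"
                )
        for name in _ANGLE_TRACKS:
            t = self.track(name)
            if np.any((t < -180.0) | (t > 180.0)):
                row = int(np.argmax((t < -180.0) | (t > 180.0))) + 1
                raise FormatError(
                    f"property table {self.protein_id!r}, row {row}: "
                    f"{name}={t[row - 1]!r} outside [-180, 180]"
                )
        asa = self.track("asa")
        if np.any(asa < 0.0):
            row = int(np.argmax(asa < 0.0)) + 1
            raise FormatError(
                f"property table {self.protein_id!r}, row {row}: negative ASA"
            )

    def check_against(self, protein: ProteinRecord) -> None:
        """Verify length and position-wise residue identity vs a sequence."""
        if self.length != len(protein):
            raise FormatError(
                f"property table {self.protein_id!r}: {self.length} rows for a "
                f"{len(protein)}-residue sequence"
            )
        for i, (a, b) in enumerate(zip(self.residues, protein.sequence)):
            if a != b:
                raise FormatError(
                    f"property table {self.protein_id!r}, row {i + 1}: residue "
                    f"{a!r} does not match sequence residue {b!r}"
                )


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated lysine site.

    ``position`` is 0-based internally; label 1 marks a phosphoglycerylated
    lysine, 0 a non-phosphoglycerylated one.
    """

    protein_id: str
    position: int
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise FormatError(
                f"site {self.protein_id}:{self.position + 1}: label must be 0 or 1"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, in file order.

    Sequences are uppercased.  Empty files, empty sequences and duplicate
    identifiers are each rejected with a distinct error message.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Property tables

#: Native dialect: tab-separated, one row per residue,
#: ``pos aa ASA pc pe ph phi psi theta tau`` (pos is 1-based).
NATIVE_DIALECT = "native"
#: Predictor dialect: whitespace-delimited
#: ``index AA SS ASA Phi Psi Theta Tau P(C) P(E) P(H)``; the one-letter
#: secondary-structure call in column 3 is read and ignored.
SPIDER_DIALECT = "spider2"

# column index (after the id/aa prefix handling below) of each track
_DIALECT_COLUMNS = {
    NATIVE_DIALECT: {
        "asa": 2, "pc": 3, "pe": 4, "ph": 5,
        "phi": 6, "psi": 7, "theta": 8, "tau": 9,
    },
    SPIDER_DIALECT: {
        "asa": 3, "phi": 4, "psi": 5, "theta": 6, "tau": 7,
        "pc": 8, "pe": 9, "ph": 10,
    },
}
_DIALECT_NCOL = {NATIVE_DIALECT: 10, SPIDER_DIALECT: 11}


def read_property_table(
    path: str | Path,
    protein_id: str | None = None,
    dialect: str = NATIVE_DIALECT,
) -> ResiduePropertyTable:
    """Read a per-residue structural-property table.

    Lines beginning with ``#`` are skipped.  Both dialects carry the same
    eight tracks; only the column order differs, so the same physical values
    read through either dialect yield identical in-memory tables.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown property-table dialect {dialect!r}")
    cols = _DIALECT_COLUMNS[dialect]
    ncol = _DIALECT_NCOL[dialect]
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem

    residues: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != ncol:
                raise FormatError(
                    f"{path}, line {lineno}: expected {ncol} columns "
                    f"({dialect} dialect), found {len(fields)}"
                )
            aa = fields[1].upper()
            if len(aa) != 1 or aa not in CANONICAL_AA:
                raise FormatError(
                    f"{path}, line {lineno}: non-canonical residue {fields[1]!r}"
                )
            try:
                row = [float(fields[cols[name]]) for name in PROPERTIES]
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: non-numeric cell ({exc})")
            residues.append(aa)
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no residue rows")
    try:
        return ResiduePropertyTable(
            protein_id=protein_id, residues="".join(residues), values=np.array(rows)
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}")


def write_property_table(
    table: ResiduePropertyTable, path: str | Path, dialect: str = NATIVE_DIALECT
) -> None:
    """Write a property table in either dialect (values at 6 decimals)."""
    with open(path, "w") as fh:
        if dialect == NATIVE_DIALECT:
            fh.write("# pos aa ASA pc pe ph phi psi theta tau\n")
            for i, aa in enumerate(table.residues):
                vals = "\t".join(f"{v:.6f}" for v in table.values[i])
                fh.write(f"{i + 1}\t{aa}\t{vals}\n")
        elif dialect == SPIDER_DIALECT:
            fh.write("# index AA SS ASA Phi Psi Theta Tau P(C) P(E) P(H)\n")
            order = ["asa", "phi", "psi", "theta", "tau", "pc", "pe", "ph"]
            for i, aa in enumerate(table.residues):
                row = {name: table.values[i, PROPERTIES.index(name)] for name in order}
                # emit a nominal SS call from the largest probability
                ss = max(("C", "pc"), ("E", "pe"), ("H", "ph"), key=lambda t: row[t[1]])[0]
                vals = " ".join(f"{row[name]:.6f}" for name in order)
                fh.write(f"{i + 1} {aa} {ss} {vals}\n")
        else:
            raise ValueError(f"unknown property-table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Site labels

def read_site_labels(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[SiteAnnotation]:
    """Read ``protein_id, position, label`` rows (comma- or tab-separated).

    Positions in the file are 1-based; every annotation is validated against
    its protein: the id must exist, the position must be in range and the
    residue there must be a lysine.
    """
    by_id = {p.id: p for p in proteins}
    annotations: list[SiteAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.replace("\t", ",").split(",")]
            if len(fields) != 3:
                raise FormatError(
                    f"{path}, line {lineno}: expected 'protein_id, position, label'"
                )
            pid, pos_s, label_s = fields
            if pid not in by_id:
                raise FormatError(f"{path}, line {lineno}: unknown protein id {pid!r}")
            try:
                pos1 = int(pos_s)
                label = int(label_s)
            except ValueError:
                raise FormatError(f"{path}, line {lineno}: non-integer position/label")
            seq = by_id[pid].sequence
            if not 1 <= pos1 <= len(seq):
                raise FormatError(
                    f"{path}, line {lineno}: position {pos1} out of range for "
                    f"{pid!r} (length {len(seq)})"
                )
            if seq[pos1 - 1] != "K":
                raise FormatError(
                    f"{path}, line {lineno}: residue at {pid}:{pos1} is "
                    f"{seq[pos1 - 1]!r}, not lysine"
                )
            annotations.append(SiteAnnotation(protein_id=pid, position=pos1 - 1, label=label))
    return annotations


def write_site_labels(annotations: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id,position,label\n")
        for a in annotations:
            fh.write(f"{a.protein_id},{a.position + 1},{a.label}\n")


# ---------------------------------------------------------------------------
# Feature-dataset files

_DATASET_PRECISION = 10  # decimals printed per feature value


def write_dataset(dataset, path: str | Path) -> None:
    """Write a :class:`~phogly.features.FeatureDataset` as self-describing CSV.

    The ``#`` header records the half-width, the active property mask and the
    column names; each data row is ``protein_id,position,label`` followed by
    the feature values at 10 decimals (the declared round-trip precision).
    """
    if len(dataset) == 0:
        raise FormatError("refusing to write an empty dataset")
    n_feat = dataset.X.shape[1]
    with open(path, "w") as fh:
        fh.write(f"# w={dataset.w}\n")
        fh.write(f"# mask={','.join(dataset.mask)}\n")
        feat_names = [
            f"f{off:+d}.{prop}"
            for off in range(-dataset.w, dataset.w + 1)
            for prop in dataset.mask
        ]
        fh.write("# columns=protein_id,position,label," + ",".join(feat_names) + "\n")
        for i in range(len(dataset)):
            pid, pos = dataset.ids[i]
            vals = ",".join(f"{v:.{_DATASET_PRECISION}f}" for v in dataset.X[i])
            fh.write(f"{pid},{pos + 1},{int(dataset.y[i])},{vals}\n")
    assert n_feat == (2 * dataset.w + 1) * len(dataset.mask)


def read_dataset(path: str | Path):
    """Read a feature-dataset file written by :func:`write_dataset`."""
    from .features import FeatureDataset  # deferred: io <-> features layering

    w = None
    mask: tuple[str, ...] | None = None
    ids: list[tuple[str, int]] = []
    labels: list[int] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("w="):
                    w = int(body[2:])
                elif body.startswith("mask="):
                    mask = tuple(body[5:].split(","))
                continue
            if w is None or mask is None:
                raise FormatError(
                    f"{path}: data row before the w=/mask= metadata header"
                )
            fields = line.split(",")
            n_expected = 3 + (2 * w + 1) * len(mask)
            if len(fields) != n_expected:
                raise FormatError(
                    f"{path}, line {lineno}: expected {n_expected} columns for "
                    f"w={w}, |mask|={len(mask)}; found {len(fields)}"
                )
            try:
                pos1 = int(fields[1])
                label = int(fields[2])
                vals = [float(v) for v in fields[3:]]
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: bad cell ({exc})")
            ids.append((fields[0], pos1 - 1))
            labels.append(label)
            rows.append(vals)
    if w is None or mask is None:
        raise FormatError(f"{path}: missing metadata header")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    bad = set(mask) - set(PROPERTIES)
    if bad:
        raise FormatError(f"{path}: unknown properties in mask: {sorted(bad)}")
    return FeatureDataset(
        X=np.array(rows), y=np.array(labels, dtype=int), ids=ids, w=w, mask=mask
    )
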