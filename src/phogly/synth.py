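"""Synthetic sequence + structural-property fixtures.

Real inputs to the pipeline are protein sequences, per-residue structural
tracks from a sequence-based structure predictor, and experimentally
confirmed phosphoglycerylation labels.  This module emulates all three so
every pipeline stage is testable end-to-end: random sequences over the 20
canonical amino acids (lysines planted at a configurable rate), baseline
property tracks drawn residue-wise from simple null distributions, and a
planted class signal — an additive mean shift of ``delta`` noise standard
deviations applied to chosen tracks at chosen window offsets around each
positive site.  ``delta = 0`` gives exchangeable classes (a null dataset);
large ``delta`` gives strongly separable ones.

Baselines: coil/strand/helix probabilities are Dirichlet(1,1,1) (so they
sum to 1 — stricter than real predictor output, which readers must not
require); the four backbone angles are Normal(0, 60 * noise_scale) degrees
clipped to [-180, 180]; ASA is Normal(60, 30 * noise_scale) Å² clipped at 0.
After a shift, probabilities are clipped and renormalised, angles clipped
to range and ASA floored at 0.

The default imbalance ratio of 29 negatives per positive mirrors the
observed regime for phosphoglycerylation (111 positive vs 3249 negative
lysines, a 1:29 ratio).
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    PROPERTIES,
    ProteinRecord,
    ResiduePropertyTable,
    SiteAnnotation,
    write_fasta,
    write_property_table,
    write_site_labels,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_NO_K = _AA.replace("K", "")

#: Per-track baseline noise SD at ``noise_scale = 1`` (the unit in which
#: the effect size ``delta`` is expressed).
TRACK_SD = {
    "asa": 30.0,
    "pc": 0.15, "pe": 0.15, "ph": 0.15,
    "phi": 60.0, "psi": 60.0, "theta": 60.0, "tau": 60.0,
}


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate the observed study regime."""

    n_proteins: int = 40
    length_range: tuple[int, int] = (60, 200)
    lysine_rate: float = 0.06
    imbalance_ratio: float = 29.0  # negatives per positive
    delta: float = 0.0  # effect size, in units of each track's noise SD
    signal_tracks: tuple[str, ...] = ("asa",)
    signal_offsets: tuple[int, ...] = (-1, 0, 1)
    noise_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("length_range must satisfy 1 <= lo <= hi")
        if not 0 < self.lysine_rate < 1:
            raise ValueError("lysine_rate must be in (0, 1)")
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance_ratio must be >= 1")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")
        bad = set(self.signal_tracks) - set(PROPERTIES)
        if bad:
            raise ValueError(f"unknown signal tracks: {sorted(bad)}")


@dataclass
class SynthBundle:
    """In-memory fixture: inputs plus the ground-truth manifest."""

    proteins: list[ProteinRecord]
    tables: dict[str, ResiduePropertyTable]
    annotations: list[SiteAnnotation]
    manifest: dict


def _baseline_tables(
    proteins: Sequence[ProteinRecord], rng: np.random.Generator, noise_scale: float
) -> dict[str, ResiduePropertyTable]:
    tables = {}
    for prot in proteins:
        L = len(prot)
        probs = rng.dirichlet(np.ones(3), size=L)  # pc, pe, ph
        angles = np.clip(
            rng.normal(0.0, 60.0 * noise_scale, size=(L, 4)), -180.0, 180.0
        )
        asa = np.clip(rng.normal(60.0, 30.0 * noise_scale, size=L), 0.0, None)
        values = np.column_stack([asa, probs, angles])
        tables[prot.id] = ResiduePropertyTable(
            protein_id=prot.id, residues=prot.sequence, values=values
        )
    return tables


def _apply_shift(
    table: ResiduePropertyTable, idx: int, tracks: Sequence[str],
    delta: float, noise_scale: float,
) -> None:
    row = table.values[idx]
    for name in tracks:
        col = PROPERTIES.index(name)
        row[col] += delta * TRACK_SD[name] * noise_scale
    # restore the per-row invariants after shifting
    row[0] = max(row[0], 0.0)
    p = np.clip(row[1:4], 0.0, None)
    total = p.sum()
    row[1:4] = p / total if total > 0 else np.array([1 / 3] * 3)
    row[4:8] = np.clip(row[4:8], -180.0, 180.0)


def simulate(config: SynthConfig) -> SynthBundle:
    """Generate an in-memory fixture bundle from a config.

    Sequences are uniform over the 20 letters except that each position is a
    lysine with probability ``lysine_rate``; every lysine becomes an
    annotated site.  Positives are sampled uniformly among sites so the
    realised negative:positive ratio matches the configured one up to
    rounding (required to stay within 10%).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    proteins: list[ProteinRecord] = []
    for i in range(config.n_proteins):
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        is_k = rng.random(L) < config.lysine_rate
        other = rng.integers(0, len(_AA_NO_K), size=L)
        seq = "".join("K" if k else _AA_NO_K[j] for k, j in zip(is_k, other))
        proteins.append(ProteinRecord(id=f"syn{i:04d}", sequence=seq))

    sites = [
        (p.id, pos)
        for p in proteins
        for pos, aa in enumerate(p.sequence)
        if aa == "K"
    ]
    n_sites = len(sites)
    if n_sites == 0:
        raise ValueError("infeasible config: no lysines generated")
    n_pos = int(round(n_sites / (1.0 + config.imbalance_ratio)))
    if n_pos == 0:
        raise ValueError(
            f"infeasible config: {n_sites} sites cannot realise a "
            f"1:{config.imbalance_ratio:g} ratio"
        )
    realized = (n_sites - n_pos) / n_pos
    if abs(realized - config.imbalance_ratio) > 0.1 * config.imbalance_ratio:
        raise ValueError(
            f"infeasible config: realised ratio {realized:.2f} deviates more "
            f"than 10% from the configured {config.imbalance_ratio:g}; "
            f"increase n_proteins or lysine_rate"
        )
    pos_idx = set(rng.choice(n_sites, size=n_pos, replace=False).tolist())

    tables = _baseline_tables(proteins, rng, config.noise_scale)
    lengths = {p.id: len(p) for p in proteins}
    annotations: list[SiteAnnotation] = []
    for s, (pid, pos) in enumerate(sites):
        label = 1 if s in pos_idx else 0
        annotations.append(SiteAnnotation(protein_id=pid, position=pos, label=label))
        if label == 1 and config.delta != 0.0:
            for off in config.signal_offsets:
                idx = pos + off
                if 0 <= idx < lengths[pid]:
                    _apply_shift(
                        tables[pid], idx, config.signal_tracks,
                        config.delta, config.noise_scale,
                    )

    manifest = {
        "config": {**asdict(config),
                   "length_range": list(config.length_range),
                   "signal_tracks": list(config.signal_tracks),
                   "signal_offsets": list(config.signal_offsets)},
        "n_sites": n_sites,
        "n_pos": n_pos,
        "n_neg": n_sites - n_pos,
        "realized_ratio": realized,
        "positives": [f"{pid}:{pos + 1}" for (pid, pos), s in
                      zip(sites, range(n_sites)) if s in pos_idx],
    }
    return SynthBundle(
        proteins=proteins, tables=tables, annotations=annotations, manifest=manifest
    )


def generate(config: SynthConfig, outdir: str | Path) -> SynthBundle:
    """Generate a fixture bundle and write it in the package's native formats.

    Emits ``proteins.fasta``, one ``<id>.prop`` table per protein under
    ``properties/``, ``sites.csv`` and ``manifest.json``; all byte-identical
    under a fixed seed and readable back through :mod:`phogly.io` unchanged.
    """
    bundle = simulate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.proteins, outdir / "proteins.fasta")
    prop_dir = outdir / "properties"
    prop_dir.mkdir(exist_ok=True)
    for pid, table in bundle.tables.items():
        write_property_table(table, prop_dir / f"{pid}.prop")
    write_site_labels(bundle.annotations, outdir / "sites.csv")
    (outdir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n"
    )
    return bundle


# ---------------------------------------------------------------------------
# Worked toy fixture

_TOY_SEQS = {
    "toy1": "MKAVKLWKDE",
    "toy2": "KKCDEFKHIKLM",
    "toy3": "AKCDKFGHKIKLMKP",
}
# (protein, 1-based position) of the three phosphoglycerylated lysines
_TOY_POSITIVES = {("toy1", 2), ("toy2", 7), ("toy3", 9)}


def make_worked_toy() -> SynthBundle:
    """A tiny fixed 12-site dataset (3 positive, 9 negative).

    Property values follow closed-form integer recipes rather than random
    draws, so regeneration is exactly reproducible and individual feature
    values can be checked by hand.  At half-width 2 with the full mask each
    site yields a 40-dimensional vector.
    """
    proteins = [ProteinRecord(id=pid, sequence=seq) for pid, seq in _TOY_SEQS.items()]
    tables: dict[str, ResiduePropertyTable] = {}
    for p_no, prot in enumerate(proteins):
        L = len(prot)
        rows = []
        for i in range(L):
            asa = 10.0 + 7.0 * ((3 * i + p_no) % 11)
            a, b, c = 1 + (i + p_no) % 3, 1 + (2 * i) % 4, 1 + (i * p_no) % 2
            total = a + b + c
            pc, pe, ph = a / total, b / total, c / total
            phi = -160.0 + 20.0 * ((i + 2 * p_no) % 16)
            psi = -150.0 + 30.0 * ((2 * i + p_no) % 11)
            theta = -90.0 + 15.0 * ((i * 3) % 12)
            tau = -170.0 + 40.0 * ((i + 5 * p_no) % 9)
            rows.append([asa, pc, pe, ph, phi, psi, theta, tau])
        tables[prot.id] = ResiduePropertyTable(
            protein_id=prot.id, residues=prot.sequence, values=np.array(rows)
        )
    annotations = [
        SiteAnnotation(
            protein_id=prot.id, position=pos,
            label=1 if (prot.id, pos + 1) in _TOY_POSITIVES else 0,
        )
        for prot in proteins
        for pos, aa in enumerate(prot.sequence)
        if aa == "K"
    ]
    manifest = {
        "n_sites": len(annotations),
        "n_pos": sum(a.label for a in annotations),
        "n_neg": sum(1 - a.label for a in annotations),
        "positives": sorted(f"{pid}:{pos}" for pid, pos in _TOY_POSITIVES),
    }
    return SynthBundle(
        proteins=proteins, tables=tables, annotations=annotations, manifest=manifest
    )
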