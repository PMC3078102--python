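"""Synthetic superfamily benchmarks with planted conserved columns.

One ancestral sequence is drawn per superfamily; family members mutate it at
a controlled substitution rate except at planted columns, where either a
fixed residue is held constant (conserved-amino-acid signal) or the residue
is resampled within a physico-chemical group (conserved-property signal).
Decoy families are pure background with no planted signal.  The generator
also emits the true MSA, so profile-HMM projection can be checked against
known column assignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import HomologyDataset, ProteinSequence, pairwise_identity
from .logic_repr import PROPERTY_GROUPS
from .profile_hmm import Alignment

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedColumn:
    """Truth record for one planted column (1-based)."""

    column: int
    kind: str  # "fixed" | "group"
    residue: str | None = None
    group: str | None = None


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic superfamily benchmark."""

    n_families: int = 2
    seqs_per_family: int = 5
    length: int = 60
    n_conserved_columns: int = 6
    conserved_column_spec: tuple[tuple[str, str], ...] = ()  # (kind, residue-or-group)
    substitution_rate: float = 0.5
    indel_rate: float = 0.0
    n_decoy_families: int = 4
    decoy_seqs_per_family: int = 5
    background: tuple[float, ...] | None = None  # None = uniform over 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conserved_columns > self.length:
            raise ValueError("more conserved columns than sequence length")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0 <= self.indel_rate <= 1:
            raise ValueError("indel_rate must be in [0, 1]")
        if self.conserved_column_spec:
            if len(self.conserved_column_spec) != self.n_conserved_columns:
                raise ValueError("conserved_column_spec length mismatch")
            for kind, value in self.conserved_column_spec:
                if kind == "fixed":
                    if value.upper() not in RESIDUES:
                        raise ValueError(f"invalid fixed residue {value!r}")
                elif kind == "group":
                    if value not in PROPERTY_GROUPS:
                        raise ValueError(f"unknown property group {value!r}")
                else:
                    raise ValueError(f"unknown planted-column kind {kind!r}")


@dataclass
class SyntheticBenchmark:
    """A generated dataset plus its ground truth."""

    dataset: HomologyDataset
    planted_columns: list[PlantedColumn]
    alignment: Alignment  # true MSA of the positive superfamily (ungapped)
    spec: FamilySpec

    def truth_json(self) -> str:
        return json.dumps(
            {
                "seed": self.spec.seed,
                "substitution_rate": self.spec.substitution_rate,
                "planted_columns": [
                    {"column": p.column, "kind": p.kind, "residue": p.residue, "group": p.group}
                    for p in self.planted_columns
                ],
            },
            indent=2,
        )


def _background(spec: FamilySpec) -> np.ndarray:
    if spec.background is None:
        return np.full(20, 1.0 / 20.0)
    p = np.asarray(spec.background, dtype=float)
    if p.shape != (20,) or not np.isclose(p.sum(), 1.0):
        raise ValueError("background must be 20 probabilities summing to 1")
    return p


def _draw(rng: np.random.Generator, p: np.ndarray, size: int) -> str:
    return "".join(RESIDUES[i] for i in rng.choice(20, size=size, p=p))


def generate_superfamily(spec: FamilySpec) -> SyntheticBenchmark:
    """Generate a labelled benchmark; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed]))
    p_bg = _background(spec)

    # Choose planted columns and their conservation rules.
    columns = sorted(rng.choice(spec.length, size=spec.n_conserved_columns, replace=False) + 1)
    planted: list[PlantedColumn] = []
    for i, col in enumerate(columns):
        if spec.conserved_column_spec:
            kind, value = spec.conserved_column_spec[i]
        else:
            kind = "fixed" if i % 2 == 0 else "group"
            value = (
                RESIDUES[rng.integers(20)]
                if kind == "fixed"
                else sorted(PROPERTY_GROUPS)[rng.integers(len(PROPERTY_GROUPS))]
            )
        if kind == "fixed":
            planted.append(PlantedColumn(column=int(col), kind="fixed", residue=value.upper()))
        else:
            planted.append(PlantedColumn(column=int(col), kind="group", group=value))

    ancestor = list(_draw(rng, p_bg, spec.length))
    for p in planted:
        if p.kind == "fixed":
            ancestor[p.column - 1] = p.residue
        else:
            members = sorted(PROPERTY_GROUPS[p.group])
            ancestor[p.column - 1] = members[rng.integers(len(members))]

    sequences: list[ProteinSequence] = []
    msa_rows: dict[str, str] = {}
    planted_idx = {p.column - 1: p for p in planted}

    for f in range(spec.n_families):
        family = f"fam{f}"
        for m in range(spec.seqs_per_family):
            core = list(ancestor)
            for i in range(spec.length):
                if i in planted_idx:
                    p = planted_idx[i]
                    # fixed columns never mutate; group columns mutate at the
                    # substitution rate but stay within the group
                    if p.kind == "group" and rng.random() < spec.substitution_rate:
                        members = sorted(PROPERTY_GROUPS[p.group])
                        core[i] = members[rng.integers(len(members))]
                elif rng.random() < spec.substitution_rate:
                    core[i] = RESIDUES[rng.integers(20)]
            sid = f"sf0_{family}_s{m}"
            msa_rows[sid] = "".join(core)
            residues = "".join(core)
            if spec.indel_rate > 0:
                # Insertions only, so true columns stay 1..length in the MSA.
                out = []
                for ch in residues:
                    out.append(ch)
                    if rng.random() < spec.indel_rate:
                        out.append(RESIDUES[rng.integers(20)])
                residues = "".join(out)
            sequences.append(
                ProteinSequence(sid, residues, family=family, superfamily="sf0")
            )

    for d in range(spec.n_decoy_families):
        family = f"decoy{d}"
        for m in range(spec.decoy_seqs_per_family):
            sid = f"neg_{family}_s{m}"
            sequences.append(
                ProteinSequence(
                    sid,
                    _draw(rng, p_bg, spec.length),
                    family=family,
                    superfamily=f"neg_sf{d}",
                )
            )

    dataset = HomologyDataset(sequences)
    return SyntheticBenchmark(
        dataset=dataset,
        planted_columns=planted,
        alignment=Alignment(msa_rows),
        spec=spec,
    )


def mean_within_family_identity(
    benchmark: SyntheticBenchmark, max_pairs: int = 40, seed: int = 0
) -> float:
    """Mean pairwise identity over (a sample of) within-family positive pairs."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    pairs = []
    for family in benchmark.dataset.families():
        members = benchmark.dataset.members(family)
        if members[0].superfamily != "sf0":
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j]))
    if not pairs:
        raise ValueError("no positive within-family pairs")
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    return float(np.mean([pairwise_identity(a, b) for a, b in pairs]))


def calibrate_identity(
    spec: FamilySpec, target: float, tolerance: float = 5.0, max_iter: int = 20
) -> FamilySpec:
    """Bisect the substitution rate until mean within-family identity ≈ target.

    Raises if the target lies below the floor imposed by planted columns
    (fixed-residue columns always match within a family).
    """
    if not 0 < target < 100:
        raise ValueError("target identity must be in (0, 100)")
    floor_spec = replace(spec, substitution_rate=1.0)
    floor = mean_within_family_identity(generate_superfamily(floor_spec))
    if target < floor - tolerance:
        raise ValueError(
            f"target {target}% below attainable floor ≈{floor:.1f}% set by "
            "planted columns"
        )
    lo, hi = 0.0, 1.0
    best = spec
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        cand = replace(spec, substitution_rate=mid)
        ident = mean_within_family_identity(generate_superfamily(cand))
        best = cand
        if abs(ident - target) <= tolerance:
            return cand
        if ident > target:
            lo = mid  # too conserved: mutate more
        else:
            hi = mid
    return best


def write_benchmark(benchmark: SyntheticBenchmark, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, aligned FASTA, manifest TSV and truth JSON to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "alignment": outdir / "superfamily_msa.afa",
        "manifest": outdir / "manifest.tsv",
        "truth": outdir / "truth.json",
    }
    with paths["fasta"].open("w") as fh:
        for s in benchmark.dataset:
            fh.write(f">{s.id}\n{s.residues}\n")
    with paths["alignment"].open("w") as fh:
        for sid, row in benchmark.alignment.rows.items():
            fh.write(f">{sid}\n{row}\n")
    with paths["manifest"].open("w") as fh:
        for s in benchmark.dataset:
            fh.write(f"{s.id}\t{s.family}\t{s.superfamily}\n")
    paths["truth"].write_text(benchmark.truth_json())
    return paths
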