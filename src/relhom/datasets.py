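"""Sequence datasets, family hierarchy, splits and balanced negative resampling.

A benchmark is a flat collection of protein sequences, each labelled with a
family and a superfamily.  Evaluation is leave-one-family-out: the target
family is the positive test set, the rest of its superfamily is the positive
training set, and everything outside the superfamily is the pool from which
balanced negative train/test sets are drawn ``T`` times.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

#: The 20 canonical amino acid one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Letters tolerated in input sequences but excluded from property counts.
NONSTANDARD_RESIDUES = frozenset("BZXUO")

_VALID_RESIDUES = CANONICAL_RESIDUES | NONSTANDARD_RESIDUES


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be interpreted as protein records."""


@dataclass(frozen=True)
class ProteinSequence:
    """One protein sequence with its family/superfamily labels.

    ``residues`` is the uppercase sequence.  Non-standard letters
    (B, Z, X, U, O) are retained — they count toward sequence length but are
    excluded from physico-chemical group membership downstream.
    """

    id: str
    residues: str
    family: str = ""
    superfamily: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HomologyDataset:
    """A collection of labelled sequences plus the family → superfamily map."""

    sequences: list[ProteinSequence]
    hierarchy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(ids) != len(set(ids)):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate sequence ids: {sorted(dupes)}")
        if not self.hierarchy:
            self.hierarchy = {s.family: s.superfamily for s in self.sequences}
        for s in self.sequences:
            if s.family not in self.hierarchy:
                raise ValueError(f"family {s.family!r} missing from hierarchy")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def by_id(self, seq_id: str) -> ProteinSequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)

    def families(self) -> list[str]:
        return sorted({s.family for s in self.sequences})

    def members(self, family: str) -> list[ProteinSequence]:
        return [s for s in self.sequences if s.family == family]


@dataclass(frozen=True)
class FamilySplit:
    """Leave-one-family-out partition for one target family."""

    target_family: str
    positive_test: tuple[str, ...]
    positive_train: tuple[str, ...]
    remaining_pool: tuple[str, ...]
    T: int

    def __post_init__(self) -> None:
        sets = (set(self.positive_test), set(self.positive_train), set(self.remaining_pool))
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split partitions overlap")
        if self.T < 1:
            raise ValueError("T must be >= 1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "target_family": self.target_family,
                "positive_test": list(self.positive_test),
                "positive_train": list(self.positive_train),
                "remaining_pool": list(self.remaining_pool),
                "T": self.T,
            },
            indent=2,
        )


@dataclass(frozen=True)
class NegativeResample:
    """One balanced draw of negative train/test ids from the remaining pool."""

    run_index: int
    negative_train: tuple[str, ...]
    negative_test: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.negative_train) & set(self.negative_test):
            raise ValueError("negative train/test overlap")


def canonicalize(residues: str) -> str:
    """Uppercase a raw sequence string and validate its alphabet."""
    seq = residues.strip().upper()
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        raise FastaParseError(f"invalid residue letters: {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read unaligned protein sequences from a FASTA file.

    Residues are uppercased; record order is preserved.  Raises
    :class:`FastaParseError` on empty files or unparseable records.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        try:
            out.append(ProteinSequence(id=rec.id, residues=canonicalize(str(rec.seq))))
        except (FastaParseError, ValueError) as exc:
            raise FastaParseError(f"record {rec.id!r} in {path}: {exc}") from exc
    return out


def read_manifest(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a ``sequence_id<TAB>family<TAB>superfamily`` manifest TSV."""
    out: dict[str, tuple[str, str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "%")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
        seq_id, family, superfamily = parts
        if seq_id in out:
            raise ValueError(f"{path}:{ln}: duplicate sequence id {seq_id!r}")
        out[seq_id] = (family, superfamily)
    return out


def load_dataset(fasta_path: str | Path, manifest_path: str | Path) -> HomologyDataset:
    """Combine a FASTA file and a manifest TSV into a labelled dataset."""
    manifest = read_manifest(manifest_path)
    sequences = []
    for seq in read_fasta(fasta_path):
        if seq.id not in manifest:
            raise ValueError(f"sequence {seq.id!r} missing from manifest")
        family, superfamily = manifest[seq.id]
        sequences.append(
            ProteinSequence(seq.id, seq.residues, family=family, superfamily=superfamily)
        )
    return HomologyDataset(sequences)


def compute_T(D: int, Tr_pos: int, Te_pos: int) -> int:
    """Number of balanced negative resamples needed to cover the pool.

    ``T = ceil(D* / (Tr+ + Te+))`` with ``D* = D - (Tr+ + Te+)``: each run
    draws one positive-set-sized negative sample, so T runs cover the
    remaining database in expectation.
    """
    pos = Tr_pos + Te_pos
    if pos <= 0:
        raise ValueError("positive set sizes must be positive")
    remaining = D - pos
    if remaining <= 0:
        raise ValueError("remaining pool is empty; cannot resample negatives")
    return max(1, math.ceil(remaining / pos))


def make_family_split(dataset: HomologyDataset, target_family: str) -> FamilySplit:
    """Build the leave-one-family-out split for ``target_family``."""
    if target_family not in dataset.hierarchy:
        raise KeyError(f"unknown family {target_family!r}")
    superfamily = dataset.hierarchy[target_family]
    positive_test, positive_train, remaining = [], [], []
    for s in dataset.sequences:
        if s.family == target_family:
            positive_test.append(s.id)
        elif s.superfamily == superfamily:
            positive_train.append(s.id)
        else:
            remaining.append(s.id)
    if not positive_train:
        raise ValueError(
            f"degenerate family {target_family!r}: no other sequences in "
            f"superfamily {superfamily!r} to train on"
        )
    T = compute_T(len(dataset), len(positive_train), len(positive_test))
    return FamilySplit(
        target_family=target_family,
        positive_test=tuple(positive_test),
        positive_train=tuple(positive_train),
        remaining_pool=tuple(remaining),
        T=T,
    )


def derive_seed(master_seed: int, *context: int | str) -> int:
    """Derive a replayable child seed from the master seed plus context tokens."""
    tokens = [master_seed] + [
        int.from_bytes(str(c).encode(), "little") % (2**32) if isinstance(c, str) else c
        for c in context
    ]
    return int(np.random.SeedSequence(tokens).generate_state(1)[0])


def sample_negatives(split: FamilySplit, run_index: int, seed: int) -> NegativeResample:
    """Draw one balanced negative train/test resample from the remaining pool.

    Sampling is uniform without replacement and fully determined by
    ``(seed, run_index)``.
    """
    n_train = len(split.positive_train)
    n_test = len(split.positive_test)
    pool = list(split.remaining_pool)
    if len(pool) < n_train + n_test:
        raise ValueError(
            f"pool of {len(pool)} cannot supply {n_train}+{n_test} negatives"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, run_index]))
    chosen = rng.choice(len(pool), size=n_train + n_test, replace=False)
    ids = [pool[i] for i in chosen]
    return NegativeResample(
        run_index=run_index,
        negative_train=tuple(ids[:n_train]),
        negative_test=tuple(ids[n_train:]),
        seed=seed,
    )


def _make_aligner(open_gap: float = 10.0, extend_gap: float = 0.5) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def _blosum_safe(residues: str) -> str:
    # BLOSUM62 covers the 20 canonical letters plus B, Z, X; map U/O to X.
    return residues.replace("U", "X").replace("O", "X")


def pairwise_identity(a: ProteinSequence, b: ProteinSequence) -> float:
    """Percent identity after Needleman-Wunsch global alignment.

    BLOSUM62, gap open 10, gap extend 0.5; identity is matches over aligned
    columns (dual-gap columns cannot occur in a pairwise alignment).
    Symmetric in its arguments.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner()
    aln = aligner.align(_blosum_safe(a.residues), _blosum_safe(b.residues))[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    columns = matches = 0
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            continue
        columns += 1
        if x == y and x != "-":
            matches += 1
    return 100.0 * matches / columns


def filter_by_identity(dataset: HomologyDataset, threshold: float) -> HomologyDataset:
    """Greedy Hobohm-1-style reduction to pairs below an identity threshold.

    Sequences are visited in descending length (ties by id); a sequence is
    kept iff its identity to every already-kept sequence is strictly below
    ``threshold``.  Families reduced to fewer than 2 sequences are dropped.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    ordered = sorted(dataset.sequences, key=lambda s: (-len(s), s.id))
    kept: list[ProteinSequence] = []
    for seq in ordered:
        if all(pairwise_identity(seq, other) < threshold for other in kept):
            kept.append(seq)
    counts: dict[str, int] = {}
    for s in kept:
        counts[s.family] = counts.get(s.family, 0) + 1
    kept = [s for s in kept if counts[s.family] >= 2]
    order = {s.id: i for i, s in enumerate(dataset.sequences)}
    kept.sort(key=lambda s: order[s.id])
    hierarchy = {s.family: s.superfamily for s in kept}
    return HomologyDataset(kept, hierarchy)
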