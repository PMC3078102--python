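"""Ground-atom representations of protein sequences.

Three representations are emitted:

* ``Seq`` — whole-sequence composition: one binned-percentage atom per
  physico-chemical group, plus binned single-residue and overlapping-dimer
  ratios.
* ``Aln_cons`` — ``col(seq, residue, column)`` atoms for conserved alignment
  positions; training rows read them off the MSA, queries obtain them via
  profile-HMM Viterbi projection.
* ``Aln_pc`` — derived ``colProp(seq, group, column)`` atoms marking
  physico-chemically conserved positions (the image of col atoms under group
  membership).

Percentages are discretized with ``bin = floor(Y / 10) + 1``, giving bins
1..11.  All constants are lower-cased; columns are 1-based.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .datasets import CANONICAL_RESIDUES, ProteinSequence
from .profile_hmm import GAP, UNALIGNED, Alignment, ProfileHMM, residue_to_column_map, viterbi

#: The 16 physico-chemical groups, name → member residues.
PROPERTY_GROUPS: dict[str, frozenset[str]] = {
    "small": frozenset("AGST"),
    "polar": frozenset("DEHKNQRSTWY"),
    "polarUncharged": frozenset("NQ"),
    "aromatic": frozenset("FHWY"),
    "charged": frozenset("DEHIKLRV"),
    "positivelyCharged": frozenset("HKR"),
    "negativelyCharged": frozenset("DE"),
    "tiny": frozenset("AG"),
    "bulky": frozenset("FHRWY"),
    "aliphatic": frozenset("ILV"),
    "hydrophobic": frozenset("ILMV"),
    "hydrophilicBasic": frozenset("KRH"),
    "hydrophilicAcidic": frozenset("EDNQ"),
    "neutralWeakHydrophobic": frozenset("AGPST"),
    "hydrophobicAromatic": frozenset("FWY"),
    "acidic": frozenset("ED"),
}

#: Representation names.
SEQ = "Seq"
ALN_CONS = "Aln_cons"
ALN_PC = "Aln_pc"
REPRESENTATIONS = (SEQ, ALN_CONS, ALN_PC)


@dataclass(frozen=True, order=True)
class GroundAtom:
    """A fully instantiated logical fact, e.g. ``col(s1, v, 1)``.

    The first argument is always the sequence identifier; remaining arguments
    are residue letters, group names, bins or column indices.  String
    constants are stored lower-cased.
    """

    predicate: str
    args: tuple[str | int, ...]

    def __str__(self) -> str:
        return f"{self.predicate}({','.join(str(a) for a in self.args)})."

    @property
    def seq_id(self) -> str:
        return str(self.args[0])


_ATOM_RE = re.compile(r"^\s*(\w+)\(([^)]*)\)\.\s*$")


def parse_atom(line: str) -> GroundAtom:
    """Parse one ``pred(a,b,c).`` line back into a :class:`GroundAtom`."""
    m = _ATOM_RE.match(line)
    if not m:
        raise ValueError(f"cannot parse ground atom: {line!r}")
    predicate = m.group(1)
    args = tuple(
        int(a) if a.strip().lstrip("-").isdigit() else a.strip()
        for a in m.group(2).split(",")
    )
    return GroundAtom(predicate, args)


@dataclass
class KnowledgeBase:
    """Ground atoms for a collection of example sequences."""

    atoms: set[GroundAtom] = field(default_factory=set)
    examples: set[str] = field(default_factory=set)
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        orphans = {a.seq_id for a in self.atoms} - self.examples
        if orphans:
            raise ValueError(f"atoms reference unknown examples: {sorted(orphans)}")

    def atoms_for(self, seq_id: str) -> set[GroundAtom]:
        return {a for a in self.atoms if a.seq_id == seq_id}

    def positives(self) -> list[str]:
        return sorted(e for e in self.examples if self.labels.get(e) == 1)

    def to_text(self) -> str:
        lines = [f"example({e})." for e in sorted(self.examples)]
        lines += [f"label({e},{v})." for e, v in sorted(self.labels.items())]
        lines += [str(a) for a in sorted(self.atoms)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "KnowledgeBase":
        atoms: set[GroundAtom] = set()
        examples: set[str] = set()
        labels: dict[str, int] = {}
        for line in text.splitlines():
            if not line.strip() or line.lstrip().startswith("%"):
                continue
            atom = parse_atom(line)
            if atom.predicate == "example":
                examples.add(str(atom.args[0]))
            elif atom.predicate == "label":
                labels[str(atom.args[0])] = int(atom.args[1])
            else:
                atoms.add(atom)
        return cls(atoms=atoms, examples=examples, labels=labels)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "KnowledgeBase":
        return cls.from_text(Path(path).read_text())


def bin_percentage(y: float) -> int:
    """Discretize a percentage into bins 1..11 via ``floor(y/10) + 1``."""
    if not 0 <= y <= 100:
        raise ValueError(f"percentage {y} out of [0, 100]")
    return math.floor(y / 10) + 1


def sequential_atoms(seq: ProteinSequence) -> set[GroundAtom]:
    """Composition atoms for one sequence.

    Emits exactly one atom per physico-chemical group (binned percentage of
    residues in the group), one ``aminoacidRatio`` atom per residue present,
    and one ``aminoacidPairRatio`` atom per distinct overlapping dimer.
    Non-standard residues count toward length but never toward numerators.
    """
    sid = seq.id
    n = len(seq.residues)
    atoms: set[GroundAtom] = set()

    for group, members in PROPERTY_GROUPS.items():
        count = sum(1 for r in seq.residues if r in members)
        atoms.add(GroundAtom(group, (sid, bin_percentage(100.0 * count / n))))

    counts: dict[str, int] = {}
    for r in seq.residues:
        if r in CANONICAL_RESIDUES:
            counts[r] = counts.get(r, 0) + 1
    for r, c in counts.items():
        atoms.add(
            GroundAtom("aminoacidRatio", (sid, r.lower(), bin_percentage(100.0 * c / n)))
        )

    if n >= 2:
        pair_counts: dict[str, int] = {}
        for a, b in zip(seq.residues, seq.residues[1:]):
            if a in CANONICAL_RESIDUES and b in CANONICAL_RESIDUES:
                pair = (a + b).lower()
                pair_counts[pair] = pair_counts.get(pair, 0) + 1
        for pair, c in pair_counts.items():
            atoms.add(
                GroundAtom(
                    "aminoacidPairRatio",
                    (sid, pair, bin_percentage(100.0 * c / (n - 1))),
                )
            )
    return atoms


def alignment_atoms_train(alignment: Alignment) -> set[GroundAtom]:
    """``col`` atoms read directly off the training MSA: one per non-gap cell."""
    atoms: set[GroundAtom] = set()
    for sid, row in alignment.rows.items():
        for col, ch in enumerate(row, start=1):
            if ch != GAP:
                atoms.add(GroundAtom("col", (sid, ch.lower(), col)))
    return atoms


def alignment_atoms_query(phmm: ProfileHMM, query: ProteinSequence) -> set[GroundAtom]:
    """``col`` atoms for a query via Viterbi projection onto the training MSA.

    Insert-state residues have no training column and emit nothing.
    """
    path = viterbi(phmm, query)
    mapping = residue_to_column_map(path, phmm, query)
    atoms: set[GroundAtom] = set()
    for pos, col in mapping.items():
        if col == UNALIGNED:
            continue
        atoms.add(GroundAtom("col", (query.id, query.residues[pos - 1].lower(), col)))
    return atoms


def physchem_column_atoms(col_atoms: Iterable[GroundAtom]) -> set[GroundAtom]:
    """Derive ``colProp(seq, group, column)`` atoms from ``col`` atoms.

    For every ``col(s, w, z)`` and every group containing ``w``, one
    ``colProp(s, group, z)`` atom is emitted.
    """
    out: set[GroundAtom] = set()
    for atom in col_atoms:
        if atom.predicate != "col":
            raise ValueError(f"expected a col atom, got {atom}")
        sid, residue, col = atom.args
        upper = str(residue).upper()
        for group, members in PROPERTY_GROUPS.items():
            if upper in members:
                out.add(GroundAtom("colProp", (sid, group, col)))
    return out


def build_kb(
    sequences: Sequence[ProteinSequence],
    representations: Iterable[str],
    phmm: ProfileHMM | None = None,
    alignment: Alignment | None = None,
    labels: Mapping[str, int] | None = None,
) -> KnowledgeBase:
    """Union of the selected representations' atoms for a set of sequences.

    Sequences that are rows of ``alignment`` contribute their alignment atoms
    directly from the MSA; all other sequences are treated as queries and
    projected through ``phmm``.
    """
    reps = set(representations)
    unknown = reps - set(REPRESENTATIONS)
    if unknown:
        raise ValueError(f"unknown representations: {sorted(unknown)}")
    needs_columns = bool(reps & {ALN_CONS, ALN_PC})
    if needs_columns and alignment is None and phmm is None:
        raise ValueError(f"{sorted(reps)} requires an alignment or a profile HMM")

    atoms: set[GroundAtom] = set()
    train_col_atoms: dict[str, set[GroundAtom]] = {}
    if needs_columns and alignment is not None:
        for atom in alignment_atoms_train(alignment):
            train_col_atoms.setdefault(atom.seq_id, set()).add(atom)

    for seq in sequences:
        if SEQ in reps:
            atoms |= sequential_atoms(seq)
        if needs_columns:
            if seq.id in train_col_atoms:
                col_atoms = train_col_atoms[seq.id]
            elif phmm is not None:
                col_atoms = alignment_atoms_query(phmm, seq)
            else:
                raise ValueError(
                    f"sequence {seq.id!r} is not an alignment row and no "
                    "profile HMM was provided for query projection"
                )
            if ALN_CONS in reps:
                atoms |= col_atoms
            if ALN_PC in reps:
                atoms |= physchem_column_atoms(col_atoms)

    kb = KnowledgeBase(
        atoms=atoms,
        examples={s.id for s in sequences},
        labels=dict(labels) if labels else {},
    )
    return kb
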