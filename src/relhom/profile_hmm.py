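"""Profile HMM construction and Viterbi decoding.

The model is the classic left-to-right match/insert/delete chain built from a
multiple sequence alignment.  Its single job here is projection: decoding a
query gives, for each query residue, the training-alignment column it
corresponds to (match states) or "unaligned" (insert states).

Architecture: nodes 1..n, one per match column.  States M_k and D_k for
k in 1..n, I_k for k in 0..n.  Decoding is global (begin-to-end), in log
space.  Ties are broken M > D > I to maximize mapped columns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
from Bio import AlignIO

from .datasets import ProteinSequence

GAP = "-"
RESIDUE_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_INDEX = {r: i for i, r in enumerate(RESIDUE_ORDER)}

#: Sentinel column value for insert-state residues.
UNALIGNED = "unaligned"


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: id → gapped row, all rows equal length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def column(self, index: int) -> str:
        """Residues of 1-based column ``index`` across all rows (with gaps)."""
        return "".join(row[index - 1] for row in self.rows.values())


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an MSA from aligned FASTA (``fmt="fasta"``) or CLUSTAL (``"clustal"``)."""
    msa = AlignIO.read(str(path), fmt)
    return Alignment({rec.id: str(rec.seq).upper() for rec in msa})


@dataclass
class ProfileHMM:
    """Match/insert/delete profile with per-node emissions and transitions.

    ``match_emissions`` has shape (n_nodes, 20); ``insert_emissions`` shape
    (n_nodes + 1, 20) — row k is insert state I_k, k = 0..n.  ``transitions``
    maps (state_kind, node) to a dict of successor (state_kind, node)
    probabilities summing to 1.  The end state is ("E", n_nodes + 1).
    """

    n_nodes: int
    match_columns: tuple[int, ...]
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: dict[tuple[str, int], dict[tuple[str, int], float]]
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 1.0 / 20.0)
    )

    def __post_init__(self) -> None:
        if self.n_nodes != len(self.match_columns):
            raise ValueError("n_nodes must equal number of match columns")
        if list(self.match_columns) != sorted(set(self.match_columns)):
            raise ValueError("match columns must be strictly increasing")
        for name, mat in (("match", self.match_emissions), ("insert", self.insert_emissions)):
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} emission rows must sum to 1")
        for state, succ in self.transitions.items():
            total = sum(succ.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"outgoing transitions of {state} sum to {total}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_nodes": self.n_nodes,
                "match_columns": list(self.match_columns),
                "match_emissions": self.match_emissions.tolist(),
                "insert_emissions": self.insert_emissions.tolist(),
                "transitions": {
                    f"{k[0]}{k[1]}": {f"{s[0]}{s[1]}": p for s, p in succ.items()}
                    for k, succ in self.transitions.items()
                },
                "background": self.background.tolist(),
            },
            indent=2,
        )


@dataclass(frozen=True)
class StatePath:
    """A decoded state sequence with its natural-log probability."""

    states: tuple[tuple[str, int], ...]
    log_probability: float

    def emitted_length(self) -> int:
        return sum(1 for kind, _ in self.states if kind in ("M", "I"))


def select_match_columns(alignment: Alignment, max_gap_fraction: float = 0.5) -> list[int]:
    """1-based columns whose gap fraction is below ``max_gap_fraction``."""
    n_rows = len(alignment.rows)
    columns = []
    for c in range(1, alignment.length + 1):
        gaps = alignment.column(c).count(GAP)
        if gaps / n_rows < max_gap_fraction:
            columns.append(c)
    return columns


def _row_state_path(row: str, match_set: frozenset[int]) -> list[tuple[str, int]]:
    """The state path a gapped alignment row implies through the model."""
    path: list[tuple[str, int]] = []
    node = 0
    for col, ch in enumerate(row, start=1):
        if col in match_set:
            node += 1
            path.append(("M", node) if ch != GAP else ("D", node))
        elif ch != GAP:
            path.append(("I", node))
    return path


def _successors(kind: str, node: int, n_nodes: int) -> list[tuple[str, int]]:
    """Legal successor states, in the canonical M > D > I preference order."""
    if node == n_nodes:
        return [("E", n_nodes + 1), ("I", node)]
    return [("M", node + 1), ("D", node + 1), ("I", node)]


def build_phmm(
    alignment: Alignment,
    pseudocount: float = 1.0,
    max_gap_fraction: float = 0.5,
) -> ProfileHMM:
    """Estimate a profile HMM from an MSA with Laplace-style pseudocounts.

    Match columns are those with gap fraction < ``max_gap_fraction``.
    Emission and transition probabilities are pseudocounted maximum-likelihood
    estimates from the alignment rows' implied state paths.
    """
    match_columns = select_match_columns(alignment, max_gap_fraction)
    if not match_columns:
        raise ValueError("alignment has no match columns under the gap rule")
    n = len(match_columns)
    match_set = frozenset(match_columns)
    a = pseudocount

    match_counts = np.zeros((n, 20))
    insert_counts = np.zeros((n + 1, 20))
    trans_counts: dict[tuple[str, int], dict[tuple[str, int], float]] = {}

    def bump(src: tuple[str, int], dst: tuple[str, int]) -> None:
        trans_counts.setdefault(src, {})[dst] = trans_counts.setdefault(src, {}).get(dst, 0.0) + 1.0

    for row in alignment.rows.values():
        path = _row_state_path(row, match_set)
        node = 0
        for col, ch in enumerate(row, start=1):
            if ch == GAP:
                if col in match_set:
                    node += 1
                continue
            if col in match_set:
                node += 1
                if ch in _RESIDUE_INDEX:
                    match_counts[node - 1, _RESIDUE_INDEX[ch]] += 1
            else:
                if ch in _RESIDUE_INDEX:
                    insert_counts[node, _RESIDUE_INDEX[ch]] += 1
        prev = ("B", 0)
        for state in path + [("E", n + 1)]:
            bump(prev, state)
            prev = state

    match_emissions = (match_counts + a) / (match_counts.sum(axis=1, keepdims=True) + 20 * a)
    insert_emissions = (insert_counts + a) / (insert_counts.sum(axis=1, keepdims=True) + 20 * a)

    transitions: dict[tuple[str, int], dict[tuple[str, int], float]] = {}
    state_space = [("B", 0)] + [
        (kind, k) for k in range(1, n + 1) for kind in ("M", "D")
    ] + [("I", k) for k in range(0, n + 1)]
    for state in state_space:
        kind, node = state
        src_node = node if kind != "B" else 0
        options = _successors("I" if kind == "B" else kind, src_node, n)
        counts = trans_counts.get(state, {})
        total = sum(counts.get(opt, 0.0) for opt in options) + a * len(options)
        transitions[state] = {opt: (counts.get(opt, 0.0) + a) / total for opt in options}

    return ProfileHMM(
        n_nodes=n,
        match_columns=tuple(match_columns),
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
    )


# State-kind preference for tie-breaking: M beats D beats I.
_KIND_RANK = {"M": 0, "D": 1, "I": 2, "B": 3}


def viterbi(phmm: ProfileHMM, query: ProteinSequence | str) -> StatePath:
    """Most probable global begin-to-end state path for ``query``.

    Dynamic programming in log space over M/I/D states; ties broken by
    preferring M over D over I so column mappings are deterministic and
    maximal.
    """
    residues = query.residues if isinstance(query, ProteinSequence) else query
    if not residues:
        raise ValueError("query must be non-empty")
    n = phmm.n_nodes
    L = len(residues)
    NEG = -math.inf

    log_match = np.log(phmm.match_emissions)
    log_insert = np.log(phmm.insert_emissions)

    def emit(kind: str, node: int, i: int) -> float:
        ch = residues[i - 1]
        if ch not in _RESIDUE_INDEX:
            return math.log(1.0 / 20.0)  # non-standard residue: background
        idx = _RESIDUE_INDEX[ch]
        return log_match[node - 1, idx] if kind == "M" else log_insert[node, idx]

    def log_t(src: tuple[str, int], dst: tuple[str, int]) -> float:
        p = phmm.transitions.get(src, {}).get(dst)
        return math.log(p) if p else NEG

    # score[(kind, node)][i]: best log-prob of a prefix path ending in that
    # state having consumed i residues.
    states = [("M", k) for k in range(1, n + 1)] + [("D", k) for k in range(1, n + 1)] + [
        ("I", k) for k in range(0, n + 1)
    ]
    score = {s: np.full(L + 1, NEG) for s in states}
    back: dict[tuple[str, int], list] = {s: [None] * (L + 1) for s in states}

    def predecessors(kind: str, node: int) -> list[tuple[str, int]]:
        preds: list[tuple[str, int]] = []
        if kind in ("M", "D"):
            src_node = node - 1
            preds = [("B", 0)] if src_node == 0 else [("M", src_node), ("D", src_node)]
            preds = preds + [("I", src_node)]
        else:  # I_node: from M_node, D_node, I_node itself, or B if node == 0
            preds = [("B", 0)] if node == 0 else [("M", node), ("D", node)]
            preds = preds + [("I", node)]
        return preds

    def best_entry(kind: str, node: int, i: int) -> tuple[float, tuple[str, int] | None]:
        best, arg = NEG, None
        for src in predecessors(kind, node):
            t = log_t(src, (kind, node))
            if t == NEG:
                continue
            prev = 0.0 if src == ("B", 0) else score[src][i]
            if src == ("B", 0) and i != 0:
                continue
            val = prev + t
            if val > best + 1e-12 or (
                arg is not None
                and abs(val - best) <= 1e-12
                and _KIND_RANK[src[0]] < _KIND_RANK[arg[0]]
            ):
                best, arg = val, src
            elif arg is None and val > NEG:
                best, arg = val, src
        return best, arg

    # Fill in order of consumed residues i, nodes ascending; D states within
    # the same i depend on lower nodes only, so node-ascending order is safe.
    for i in range(0, L + 1):
        for node in range(0, n + 1):
            if node >= 1 and i >= 1:
                val, arg = best_entry("M", node, i - 1)
                if arg is not None:
                    score[("M", node)][i] = val + emit("M", node, i)
                    back[("M", node)][i] = arg
            if node >= 1:
                val, arg = best_entry("D", node, i)
                if arg is not None:
                    score[("D", node)][i] = val
                    back[("D", node)][i] = arg
            if i >= 1:
                val, arg = best_entry("I", node, i - 1)
                if arg is not None:
                    score[("I", node)][i] = val + emit("I", node, i)
                    back[("I", node)][i] = arg

    # Termination: into the end state from M_n, D_n, I_n with all L consumed.
    end_best, end_arg = NEG, None
    for src in [("M", n), ("D", n), ("I", n)]:
        t = log_t(src, ("E", n + 1))
        if t == NEG:
            continue
        val = score[src][L] + t
        if end_arg is None or val > end_best + 1e-12 or (
            abs(val - end_best) <= 1e-12 and _KIND_RANK[src[0]] < _KIND_RANK[end_arg[0]]
        ):
            if val > NEG:
                end_best, end_arg = val, src
    if end_arg is None:
        raise RuntimeError("no legal path through the model (should not happen)")

    # Traceback.
    path: list[tuple[str, int]] = []
    state, i = end_arg, L
    while state != ("B", 0):
        path.append(state)
        prev = back[state][i]
        if state[0] in ("M", "I"):
            i -= 1
        state = prev
    path.reverse()
    return StatePath(states=tuple(path), log_probability=end_best)


def residue_to_column_map(
    path: StatePath, phmm: ProfileHMM, query: ProteinSequence | str
) -> dict[int, int | str]:
    """Map 1-based query positions to training-alignment columns.

    Match-state residues map to their node's alignment column; insert-state
    residues map to :data:`UNALIGNED`.  Columns visited by delete states get
    no entry.
    """
    residues = query.residues if isinstance(query, ProteinSequence) else query
    if path.emitted_length() != len(residues):
        raise ValueError(
            f"path emits {path.emitted_length()} residues but query has {len(residues)}"
        )
    mapping: dict[int, int | str] = {}
    pos = 0
    for kind, node in path.states:
        if kind == "M":
            pos += 1
            mapping[pos] = phmm.match_columns[node - 1]
        elif kind == "I":
            pos += 1
            mapping[pos] = UNALIGNED
    return mapping
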