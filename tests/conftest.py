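"""Shared fixtures and independent oracles for the test suite.

The oracles here (exhaustive path enumeration, brute-force subset mining,
pair-counting AUC) deliberately share no code with the implementations they
check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from relhom.datasets import ProteinSequence
from relhom.logic_repr import GroundAtom, KnowledgeBase
from relhom.pattern_miner import LanguageBias, Pattern, atom_to_literal, _literal_key
from relhom.profile_hmm import RESIDUE_ORDER, ProfileHMM

_RESIDUE_INDEX = {r: i for i, r in enumerate(RESIDUE_ORDER)}


# ---------------------------------------------------------------- oracles


def enumerate_best_path(phmm: ProfileHMM, residues: str) -> float:
    """Brute-force maximum log-probability over all legal begin-to-end paths."""
    L = len(residues)
    best = [-math.inf]

    def emission(kind: str, node: int, i: int) -> float:
        idx = _RESIDUE_INDEX[residues[i]]
        if kind == "M":
            return math.log(phmm.match_emissions[node - 1, idx])
        return math.log(phmm.insert_emissions[node, idx])

    def rec(state: tuple[str, int], consumed: int, logp: float) -> None:
        for succ, p in phmm.transitions[state].items():
            lp = logp + math.log(p)
            kind, node = succ
            if kind == "E":
                if consumed == L and lp > best[0]:
                    best[0] = lp
            elif kind in ("M", "I"):
                if consumed < L:
                    rec(succ, consumed + 1, lp + emission(kind, node, consumed))
            else:  # D
                rec(succ, consumed, lp)

    rec(("B", 0), 0, 0.0)
    return best[0]


def brute_force_mine(kb: KnowledgeBase, bias: LanguageBias) -> set[tuple]:
    """All frequent bodies by exhaustive subset enumeration (set of bodies)."""
    positives = kb.positives() if kb.labels else sorted(kb.examples)
    literals = sorted(
        {
            atom_to_literal(a)
            for a in kb.atoms
            if a.seq_id in positives
            and (bias.predicates is None or a.predicate in bias.predicates)
        },
        key=_literal_key,
    )
    n = len(positives)
    min_count = bias.min_confidence * n - 1e-9
    out: set[tuple] = set()
    for k in range(1, bias.max_length + 1):
        for combo in itertools.combinations(literals, k):
            covered = sum(
                1
                for e in positives
                if all(
                    GroundAtom(pred, (e,) + tuple(args)) in kb.atoms
                    for pred, args in combo
                )
            )
            if covered >= min_count:
                out.add(combo)
    return out


def pair_counting_auc(scores, labels) -> float:
    """AUC by explicit counting over every (positive, negative) pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def random_kb(rng: np.random.Generator, max_examples: int = 6, max_atoms: int = 12) -> KnowledgeBase:
    """A small random knowledge base for miner-oracle comparisons."""
    n_examples = int(rng.integers(2, max_examples + 1))
    examples = {f"e{i}" for i in range(n_examples)}
    predicates = ["col", "hydrophobic", "aminoacidRatio"]
    distinct = []
    for _ in range(int(rng.integers(3, max_atoms + 1))):
        pred = predicates[rng.integers(len(predicates))]
        if pred == "col":
            args = (RESIDUE_ORDER[rng.integers(20)].lower(), int(rng.integers(1, 6)))
        elif pred == "hydrophobic":
            args = (int(rng.integers(1, 12)),)
        else:
            args = (RESIDUE_ORDER[rng.integers(20)].lower(), int(rng.integers(1, 12)))
        distinct.append((pred, args))
    atoms = set()
    for e in examples:
        for pred, args in distinct:
            if rng.random() < 0.5:
                atoms.add(GroundAtom(pred, (e,) + args))
    return KnowledgeBase(atoms=atoms, examples=examples, labels={e: 1 for e in examples})


def random_phmm(rng: np.random.Generator, n_nodes: int) -> ProfileHMM:
    """A random (but valid) profile HMM for Viterbi-oracle comparisons."""

    def simplex(k: int) -> np.ndarray:
        v = rng.dirichlet(np.ones(k))
        return v

    match_emissions = np.vstack([simplex(20) for _ in range(n_nodes)])
    insert_emissions = np.vstack([simplex(20) for _ in range(n_nodes + 1)])
    transitions = {}
    states = [("B", 0)] + [(k, n) for n in range(1, n_nodes + 1) for k in ("M", "D")] + [
        ("I", n) for n in range(0, n_nodes + 1)
    ]
    for kind, node in states:
        if node == n_nodes and kind != "B":
            options = [("E", n_nodes + 1), ("I", node)]
        else:
            options = [("M", node + 1), ("D", node + 1), ("I", node)]
        probs = simplex(len(options))
        transitions[(kind, node)] = {opt: float(p) for opt, p in zip(options, probs)}
    return ProfileHMM(
        n_nodes=n_nodes,
        match_columns=tuple(range(1, n_nodes + 1)),
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
    )


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def toy_sequences() -> list[ProteinSequence]:
    return [
        ProteinSequence("s1", "ACDGK", family="famA", superfamily="sfX"),
        ProteinSequence("s2", "ACDGL", family="famA", superfamily="sfX"),
        ProteinSequence("s3", "ACEGK", family="famB", superfamily="sfX"),
        ProteinSequence("s4", "WWWWW", family="famC", superfamily="sfY"),
        ProteinSequence("s5", "YYYYY", family="famC", superfamily="sfY"),
    ]


@pytest.fixture
def toy_kb() -> KnowledgeBase:
    """Hand-built KB: 4 positives; col(A,c,5) holds for 3 of them."""
    atoms = set()
    for e in ("e1", "e2", "e3"):
        atoms.add(GroundAtom("col", (e, "c", 5)))
    atoms.add(GroundAtom("col", ("e1", "k", 2)))
    atoms.add(GroundAtom("col", ("e2", "k", 2)))
    atoms.add(GroundAtom("col", ("e4", "v", 1)))
    return KnowledgeBase(
        atoms=atoms,
        examples={"e1", "e2", "e3", "e4"},
        labels={e: 1 for e in ("e1", "e2", "e3", "e4")},
    )
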