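"""Level-wise frequent relational pattern mining over the positive examples.

Patterns are conjunctive bodies ``homologous(A) :- lit_1, ..., lit_k`` whose
literals share the example variable ``A`` and are otherwise fully
instantiated with constants observed in the positive knowledge base.
Confidence is the fraction of positive examples covered by the body, and it
is anti-monotone in body extension, which supports APRIORI-style level-wise
search with pruning.

Coverage is evaluated on bitmask representations of each literal's covered
example set, so candidate evaluation is a single integer AND.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .logic_repr import GroundAtom, KnowledgeBase

#: A literal: a predicate applied to the example variable A plus constants.
Literal = tuple[str, tuple[str | int, ...]]


def atom_to_literal(atom: GroundAtom) -> Literal:
    """Abstract a ground atom into a literal by replacing its example id with A."""
    return (atom.predicate, atom.args[1:])


def literal_to_str(lit: Literal) -> str:
    pred, args = lit
    rendered = ",".join(["A"] + [str(a) for a in args])
    return f"{pred}({rendered})"


def _literal_key(lit: Literal) -> tuple:
    pred, args = lit
    return (pred,) + tuple((type(a).__name__, a) for a in args)


@dataclass(frozen=True)
class Pattern:
    """A conjunctive rule body with its confidence on the positive examples."""

    body: tuple[Literal, ...]
    confidence: float

    @property
    def length(self) -> int:
        return len(self.body)

    def to_prolog(self) -> str:
        if not self.body:
            return f"homologous(A). % {self.confidence:.2f}"
        lits = ", ".join(literal_to_str(l) for l in self.body)
        return f"homologous(A) :- {lits}. % {self.confidence:.2f}"

    def pretty(self) -> str:
        """Render colProp literals in the two-literal col/group form."""
        parts = []
        for pred, args in self.body:
            if pred == "colProp":
                group, col = args
                parts.append(f"col(A,B,{col}), {group}(B)")
            else:
                parts.append(literal_to_str((pred, args)))
        body = ", ".join(parts) if parts else "true"
        return f"homologous(A) :- {body}. % {self.confidence:.2f}"


@dataclass(frozen=True)
class LanguageBias:
    """Search-space bounds for the miner."""

    max_length: int = 3
    min_confidence: float = 0.25
    predicates: frozenset[str] | None = None  # None = all predicates in the KB

    def __post_init__(self) -> None:
        if not 0 < self.min_confidence <= 1:
            raise ValueError("min_confidence must be in (0, 1]")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")


def covers(pattern: Pattern | Sequence[Literal], kb: KnowledgeBase, example_id: str) -> bool:
    """True iff every body literal, with A bound to ``example_id``, is in the KB."""
    if example_id not in kb.examples:
        raise KeyError(f"unknown example {example_id!r}")
    body = pattern.body if isinstance(pattern, Pattern) else tuple(pattern)
    return all(
        GroundAtom(pred, (example_id,) + tuple(args)) in kb.atoms for pred, args in body
    )


def confidence(pattern: Pattern | Sequence[Literal], kb: KnowledgeBase) -> float:
    """Fraction of positive examples covered by the pattern body."""
    positives = kb.positives() if kb.labels else sorted(kb.examples)
    if not positives:
        raise ValueError("knowledge base has no positive examples")
    covered = sum(1 for e in positives if covers(pattern, kb, e))
    return covered / len(positives)


def _positive_literal_masks(
    kb: KnowledgeBase, bias: LanguageBias
) -> tuple[list[str], dict[Literal, int]]:
    """Coverage bitmask over the positive examples for every observed literal."""
    positives = kb.positives() if kb.labels else sorted(kb.examples)
    index = {e: i for i, e in enumerate(positives)}
    masks: dict[Literal, int] = {}
    for atom in kb.atoms:
        if atom.seq_id not in index:
            continue
        if bias.predicates is not None and atom.predicate not in bias.predicates:
            continue
        lit = atom_to_literal(atom)
        masks[lit] = masks.get(lit, 0) | (1 << index[atom.seq_id])
    return positives, masks


def refine(
    pattern: Pattern, bias: LanguageBias, kb: KnowledgeBase
) -> list[Pattern]:
    """Length+1 extensions of ``pattern`` by literals canonically after its last.

    Candidate literals are the distinct atoms-as-literals observed on the
    positive examples; confidences are computed on the KB.  Used mainly for
    inspection — :func:`mine` runs the same refinement internally on bitmasks.
    """
    positives, masks = _positive_literal_masks(kb, bias)
    ordered = sorted(masks, key=_literal_key)
    last = pattern.body[-1] if pattern.body else None
    out = []
    for lit in ordered:
        if last is not None and _literal_key(lit) <= _literal_key(last):
            continue
        body = pattern.body + (lit,)
        out.append(Pattern(body=body, confidence=confidence(body, kb)))
    return out


def mine(kb_positive: KnowledgeBase, bias: LanguageBias) -> list[Pattern]:
    """All patterns of length ≤ max_length with confidence ≥ min_confidence.

    Level-wise search: level 1 enumerates distinct observed literals; each
    subsequent level extends surviving patterns with canonically greater
    literals, pruning by the anti-monotone confidence bound.  Output order is
    deterministic: by length, then canonical body order.
    """
    positives, masks = _positive_literal_masks(kb_positive, bias)
    if not positives:
        raise ValueError("knowledge base has no positive examples")
    n = len(positives)
    min_count = bias.min_confidence * n - 1e-9

    ordered = sorted(masks, key=_literal_key)
    lit_rank = {lit: i for i, lit in enumerate(ordered)}

    results: list[Pattern] = []
    # frontier: list of (body, mask) surviving at the current level
    frontier: list[tuple[tuple[Literal, ...], int]] = []
    for lit in ordered:
        mask = masks[lit]
        if mask.bit_count() >= min_count:
            frontier.append(((lit,), mask))
            results.append(Pattern(body=(lit,), confidence=mask.bit_count() / n))

    level = 1
    while frontier and level < bias.max_length:
        nxt: list[tuple[tuple[Literal, ...], int]] = []
        for body, mask in frontier:
            start = lit_rank[body[-1]] + 1
            for lit in ordered[start:]:
                new_mask = mask & masks[lit]
                if new_mask.bit_count() >= min_count:
                    new_body = body + (lit,)
                    nxt.append((new_body, new_mask))
                    results.append(
                        Pattern(body=new_body, confidence=new_mask.bit_count() / n)
                    )
        frontier = nxt
        level += 1

    results.sort(key=lambda p: (p.length, tuple(_literal_key(l) for l in p.body)))
    return results


def save_rules(patterns: Iterable[Pattern], path: str | Path) -> None:
    """Write rules as Prolog-like text with trailing confidences."""
    Path(path).write_text("".join(p.to_prolog() + "\n" for p in patterns))


def rules_to_json(patterns: Iterable[Pattern]) -> str:
    return json.dumps(
        [
            {
                "body": [[pred, list(args)] for pred, args in p.body],
                "confidence": p.confidence,
            }
            for p in patterns
        ],
        indent=2,
    )


def rules_from_json(text: str) -> list[Pattern]:
    out = []
    for entry in json.loads(text):
        body = tuple((pred, tuple(args)) for pred, args in entry["body"])
        out.append(Pattern(body=body, confidence=entry["confidence"]))
    return out
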