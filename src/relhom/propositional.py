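"""Propositionalization of mined rules and attribute-value classifiers.

Each mined rule becomes one binary attribute: 1 for an example iff the
rule's body query succeeds on that example's ground atoms.  The resulting
binary matrix trains either an RBF-kernel SVM or a decision tree; continuous
scores (SVM decision values, tree positive-class probabilities) feed the
ROC analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .logic_repr import KnowledgeBase
from .pattern_miner import Pattern

SVM_RBF = "SVM-RBF"
DECISION_TREE = "DecisionTree"


class EmptyRuleSetError(ValueError):
    """No rules to propositionalize — lower the mining/selection thresholds."""


@dataclass
class FeatureMatrix:
    """Examples × rules binary matrix with optional class labels."""

    example_ids: list[str]
    rule_ids: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.example_ids), len(self.rule_ids)):
            raise ValueError("matrix shape inconsistent with id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("feature values must be binary")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.example_ids),):
                raise ValueError("label vector length mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.example_ids, columns=self.rule_ids)
        df.index.name = "example_id"
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="example_id")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy()
        return cls(
            example_ids=[str(i) for i in df.index],
            rule_ids=list(df.columns),
            values=df.to_numpy(),
            labels=labels,
        )


@dataclass
class TrainedModel:
    """A fitted classifier plus the rule ids it expects at test time."""

    kind: str
    estimator: object
    rule_ids: list[str]
    seed: int
    metadata: dict = field(default_factory=dict)

    def _check(self, matrix: FeatureMatrix) -> None:
        if matrix.rule_ids != self.rule_ids:
            raise ValueError(
                f"feature mismatch: model expects {len(self.rule_ids)} rules, "
                f"matrix has {len(matrix.rule_ids)}"
            )


def rule_id(index: int) -> str:
    return f"r{index + 1}"


def propositionalize(
    rules: Sequence[Pattern],
    kb: KnowledgeBase,
    example_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Binary coverage matrix: entry (e, r) = 1 iff rule r covers example e."""
    if not rules:
        raise EmptyRuleSetError(
            "no rules to propositionalize; lower min_confidence or the "
            "chi-square delta"
        )
    ids = list(example_ids) if example_ids is not None else sorted(kb.examples)
    if not ids:
        raise ValueError("no examples to propositionalize")
    unknown = set(ids) - kb.examples
    if unknown:
        raise KeyError(f"unknown examples: {sorted(unknown)}")
    # Vectorized conjunctive-query evaluation: per-literal coverage vectors,
    # rule column = AND over its literals.  Equivalent to covers() per entry.
    index = {e: i for i, e in enumerate(ids)}
    coverage: dict = {}
    for atom in kb.atoms:
        i = index.get(atom.seq_id)
        if i is None:
            continue
        lit = (atom.predicate, atom.args[1:])
        vec = coverage.get(lit)
        if vec is None:
            vec = coverage[lit] = np.zeros(len(ids), dtype=bool)
        vec[i] = True
    values = np.zeros((len(ids), len(rules)), dtype=np.int8)
    for j, rule in enumerate(rules):
        col = np.ones(len(ids), dtype=bool)
        for lit in rule.body:
            vec = coverage.get(lit)
            if vec is None:
                col[:] = False
                break
            col &= vec
        values[:, j] = col
    labels = None
    if kb.labels:
        labels = np.array([kb.labels[e] for e in ids], dtype=np.int8)
    return FeatureMatrix(
        example_ids=ids,
        rule_ids=[rule_id(j) for j in range(len(rules))],
        values=values,
        labels=labels,
    )


def chi_square_select(
    matrix: FeatureMatrix, delta: float
) -> tuple[FeatureMatrix, list[int]]:
    """Keep features whose 2×2 chi-square independence test gives p ≤ delta.

    The observed table crosses feature value (1/0) with class (+/−); no
    continuity correction.  Degenerate features (constant columns) have
    statistic 0 and are removed at any delta < 1.  Returns the reduced
    matrix and the retained column indices.
    """
    if matrix.labels is None:
        raise ValueError("chi-square selection requires labels")
    y = matrix.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for chi-square selection")
    kept: list[int] = []
    for j in range(matrix.values.shape[1]):
        x = matrix.values[:, j]
        table = np.array(
            [
                [np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
                [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))],
            ]
        )
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            p = 1.0  # constant feature (or degenerate class margin): independent
        else:
            _, p, _, _ = chi2_contingency(table, correction=False)
        if p <= delta:
            kept.append(j)
    reduced = FeatureMatrix(
        example_ids=list(matrix.example_ids),
        rule_ids=[matrix.rule_ids[j] for j in kept],
        values=matrix.values[:, kept] if kept else np.zeros((len(matrix.example_ids), 0), dtype=np.int8),
        labels=None if matrix.labels is None else matrix.labels.copy(),
    ) if kept else None
    if reduced is None:
        raise EmptyRuleSetError(
            f"chi-square at delta={delta} removed all rules; raise delta or "
            "disable selection"
        )
    return reduced, kept


def chi_square_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Chi-square statistic of the 2×2 (feature × class) table, no correction."""
    table = np.array(
        [
            [np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
            [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))],
        ]
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return 0.0
    stat, _, _, _ = chi2_contingency(table, correction=False)
    return float(stat)


def train(matrix: FeatureMatrix, kind: str, seed: int) -> TrainedModel:
    """Fit an RBF-kernel SVM or a decision tree on a binary feature matrix.

    Hyperparameters are library defaults; features are used as raw 0/1
    values with no scaling.
    """
    if matrix.labels is None:
        raise ValueError("training requires labels")
    if len(np.unique(matrix.labels)) < 2:
        raise ValueError("training requires both classes")
    if matrix.values.shape[1] == 0:
        raise ValueError("training requires at least one feature")
    if (matrix.values.std(axis=0) == 0).all():
        raise ValueError("degenerate feature matrix: every column is constant")
    if kind == SVM_RBF:
        estimator = SVC(kernel="rbf", random_state=seed)
    elif kind == DECISION_TREE:
        estimator = DecisionTreeClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    estimator.fit(matrix.values, matrix.labels)
    return TrainedModel(kind=kind, estimator=estimator, rule_ids=list(matrix.rule_ids), seed=seed)


def score(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Per-example continuous scores; higher means more homologous-like."""
    model._check(matrix)
    if model.kind == SVM_RBF:
        return np.asarray(model.estimator.decision_function(matrix.values), dtype=float)
    proba = model.estimator.predict_proba(matrix.values)
    positive_column = list(model.estimator.classes_).index(1)
    return np.asarray(proba[:, positive_column], dtype=float)
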