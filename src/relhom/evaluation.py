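"""Leave-one-family-out assessment with balanced negative resampling.

For each target family the pipeline is run ``T`` times over the fixed
positive sets and freshly resampled balanced negative sets.  Each run yields
an AUC-ROC on the test examples; per-family performance is the mean over
runs, overall performance the unweighted mean over families.  Methods are
compared with the two-sided Wilcoxon rank-sum test on per-family means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

from . import propositional
from .datasets import (
    FamilySplit,
    HomologyDataset,
    NegativeResample,
    derive_seed,
    make_family_split,
    sample_negatives,
)
from .logic_repr import (
    ALN_CONS,
    ALN_PC,
    PROPERTY_GROUPS,
    REPRESENTATIONS,
    SEQ,
    KnowledgeBase,
    build_kb,
)
from .pattern_miner import LanguageBias, Pattern, mine
from .profile_hmm import Alignment, ProfileHMM, build_phmm

#: Mining confidence thresholds per representation (defaults: 25%/25%/50%).
DEFAULT_MIN_CONFIDENCE = {SEQ: 0.25, ALN_CONS: 0.25, ALN_PC: 0.50}

_REP_PREDICATES = {
    SEQ: frozenset({"aminoacidRatio", "aminoacidPairRatio"} | set(PROPERTY_GROUPS)),
    ALN_CONS: frozenset({"col"}),
    ALN_PC: frozenset({"colProp"}),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one end-to-end run."""

    representations: tuple[str, ...] = (SEQ, ALN_CONS, ALN_PC)
    min_confidence: dict | None = None  # representation → threshold
    max_length: int = 3
    classifier: str = propositional.SVM_RBF
    chi_square_delta: float | None = None
    seed: int = 0

    def thresholds(self) -> dict[str, float]:
        out = dict(DEFAULT_MIN_CONFIDENCE)
        if self.min_confidence:
            out.update(self.min_confidence)
        return out


@dataclass
class FamilyResult:
    family: str
    per_run_auc: list[float]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_run_auc))


@dataclass
class BenchmarkResult:
    method: str
    families: list[FamilyResult]

    @property
    def overall_auc(self) -> float:
        return float(np.mean([f.mean_auc for f in self.families]))

    def family_means(self) -> list[float]:
        return [f.mean_auc for f in self.families]

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "overall_auc": self.overall_auc,
                "families": {
                    f.family: {"per_run_auc": f.per_run_auc, "mean_auc": f.mean_auc}
                    for f in self.families
                },
            },
            indent=2,
        )

    def save_tsv(self, path: str | Path) -> None:
        lines = ["family\trun\tauc"]
        for f in self.families:
            for t, auc in enumerate(f.per_run_auc, start=1):
                lines.append(f"{f.family}\t{t}\t{auc:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def auc_roc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: P(score+ > score-) + 0.5 P(tie), via midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    rank_sum = float(np.sum(ranks[labels == 1]))
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def rank_sum_compare(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing two AUC samples.

    Exact when sample sizes are small and tie-free, otherwise the normal
    approximation with tie correction.  Fully tied data (zero rank variance)
    returns 1.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    _, p = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(p)


def auc_vs_family_curve(result: BenchmarkResult) -> list[tuple[float, int]]:
    """Step curve: for each threshold, number of families with mean AUC ≥ it."""
    means = sorted(result.family_means())
    if not means:
        raise ValueError("no families in result")
    thresholds = sorted(set([0.0] + means))
    return [(t, sum(1 for m in means if m >= t)) for t in thresholds]


def save_curve_csv(result: BenchmarkResult, path: str | Path) -> None:
    """Write the AUC-vs-families step curve as ``threshold,n_families`` CSV."""
    lines = ["auc_threshold,n_families"]
    lines += [f"{t:.6f},{c}" for t, c in auc_vs_family_curve(result)]
    Path(path).write_text("\n".join(lines) + "\n")


def _trivial_alignment(sequences) -> Alignment:
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(
            "positive training sequences have unequal lengths; provide a "
            "precomputed alignment (e.g. the generator's true MSA or an "
            "external aligner's output)"
        )
    return Alignment({s.id: s.residues for s in sequences})


def mine_rules(
    kb_train_positive: KnowledgeBase, config: PipelineConfig
) -> list[Pattern]:
    """Mine each selected representation at its own threshold and concatenate."""
    thresholds = config.thresholds()
    rules: list[Pattern] = []
    for rep in config.representations:
        bias = LanguageBias(
            max_length=config.max_length,
            min_confidence=thresholds[rep],
            predicates=_REP_PREDICATES[rep],
        )
        rules.extend(mine(kb_train_positive, bias))
    return rules


@dataclass
class RunRecord:
    """Diagnostics for one negative resample run."""

    run_index: int
    auc: float
    n_rules: int
    n_selected: int


def evaluate_family(
    dataset: HomologyDataset,
    split: FamilySplit,
    config: PipelineConfig,
    alignment: Alignment | None = None,
    shuffle_labels: bool = False,
) -> FamilyResult:
    """Run the full pipeline T times for one family and return per-run AUCs.

    Per run: sample balanced negatives, build train/test knowledge bases
    (profile HMM built from the positive-training alignment only), mine rules
    on the positive training KB, propositionalize, optionally chi-square
    select, train, score the test examples and compute AUC.

    ``alignment`` overrides the positive-training MSA; without it the
    training sequences must be equal-length (trivially alignable), as
    produced by the synthetic generator.  ``shuffle_labels`` permutes the
    example-label association (train and test) per run — a null-distribution
    control that should score at chance.
    """
    pos_train = [dataset.by_id(i) for i in split.positive_train]
    pos_test = [dataset.by_id(i) for i in split.positive_test]
    if alignment is not None:
        # Restrict to positive-training rows: the model must never see test
        # rows of the alignment.
        rows = {i: alignment.rows[i] for i in split.positive_train if i in alignment.rows}
        if len(rows) != len(split.positive_train):
            missing = set(split.positive_train) - set(rows)
            raise ValueError(f"alignment lacks positive training rows: {sorted(missing)}")
        aln = Alignment(rows)
    else:
        aln = _trivial_alignment(pos_train)

    needs_columns = bool(set(config.representations) & {ALN_CONS, ALN_PC})
    phmm = build_phmm(aln) if needs_columns else None

    kb_pos_train = build_kb(
        pos_train, config.representations, phmm=phmm, alignment=aln,
        labels={s.id: 1 for s in pos_train},
    )
    rules = mine_rules(kb_pos_train, config)
    if not rules:
        raise propositional.EmptyRuleSetError(
            f"no rules mined for family {split.target_family!r}; lower the "
            "confidence thresholds"
        )

    # Query atoms are deterministic per sequence: cache across runs.
    atom_cache: dict[str, KnowledgeBase] = {}

    def query_kb(sequences, labels) -> KnowledgeBase:
        atoms = set()
        for s in sequences:
            if s.id not in atom_cache:
                atom_cache[s.id] = build_kb([s], config.representations, phmm=phmm, alignment=aln)
            atoms |= atom_cache[s.id].atoms
        return KnowledgeBase(atoms=atoms, examples={s.id for s in sequences}, labels=labels)

    per_run: list[float] = []
    for run_index in range(1, split.T + 1):
        run_seed = derive_seed(config.seed, split.target_family, run_index)
        resample = sample_negatives(split, run_index, run_seed)
        neg_train = [dataset.by_id(i) for i in resample.negative_train]
        neg_test = [dataset.by_id(i) for i in resample.negative_test]

        train_labels = {s.id: 1 for s in pos_train} | {s.id: 0 for s in neg_train}
        test_labels = {s.id: 1 for s in pos_test} | {s.id: 0 for s in neg_test}
        kb_train = query_kb(pos_train + neg_train, train_labels)
        kb_test = query_kb(pos_test + neg_test, test_labels)

        train_ids = [s.id for s in pos_train + neg_train]
        test_ids = [s.id for s in pos_test + neg_test]
        m_train = propositional.propositionalize(rules, kb_train, train_ids)
        m_test = propositional.propositionalize(rules, kb_test, test_ids)

        if shuffle_labels:
            # Null control: break the example-label association for the whole
            # run.  Shuffling only the training labels is not a usable null
            # here — mined features cluster the positives tightly, so a
            # noise-trained kernel machine still recovers the cluster axis
            # with a random sign and per-run AUC degenerates to {0, 1}.
            rng = np.random.default_rng(np.random.SeedSequence([run_seed, 7]))
            m_train.labels = rng.permutation(m_train.labels)
            shuffled_test = rng.permutation([test_labels[i] for i in test_ids])
            test_labels = dict(zip(test_ids, shuffled_test))

        active_rules = rules
        if config.chi_square_delta is not None:
            m_train, kept = propositional.chi_square_select(m_train, config.chi_square_delta)
            m_test = propositional.FeatureMatrix(
                example_ids=list(m_test.example_ids),
                rule_ids=[m_test.rule_ids[j] for j in kept],
                values=m_test.values[:, kept],
                labels=m_test.labels,
            )
            active_rules = [rules[j] for j in kept]
            m_train.rule_ids = [propositional.rule_id(j) for j in range(len(kept))]
            m_test.rule_ids = list(m_train.rule_ids)

        model = propositional.train(m_train, config.classifier, seed=run_seed)
        scores = propositional.score(model, m_test)
        labels = np.array([test_labels[i] for i in test_ids])
        per_run.append(auc_roc(scores, labels))

    return FamilyResult(family=split.target_family, per_run_auc=per_run)


def evaluate_benchmark(
    dataset: HomologyDataset,
    config: PipelineConfig,
    method_name: str | None = None,
    alignments: dict[str, Alignment] | None = None,
    families: Iterable[str] | None = None,
    shuffle_labels: bool = False,
) -> BenchmarkResult:
    """Leave-one-family-out evaluation over all (eligible) families."""
    name = method_name or f"{config.classifier}-" + "-".join(config.representations)
    results = []
    targets = list(families) if families is not None else dataset.families()
    for family in targets:
        try:
            split = make_family_split(dataset, family)
        except ValueError:
            continue  # degenerate family: no positive training data
        aln = (alignments or {}).get(family)
        results.append(
            evaluate_family(dataset, split, config, alignment=aln, shuffle_labels=shuffle_labels)
        )
    if not results:
        raise ValueError("no evaluable families in dataset")
    return BenchmarkResult(method=name, families=results)
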