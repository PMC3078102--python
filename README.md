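# relhom

Relational-pattern-based remote protein homology detection.

Protein sequences and multiple sequence alignments are encoded as
first-order-logic ground atoms; a level-wise relational pattern miner
extracts frequent conjunctive rules from the positive training family; the
rules are propositionalized into binary features that train an RBF-kernel
SVM or a decision tree; evaluation follows a leave-one-family-out protocol
with balanced negative resampling and averaged AUC-ROC.

## Layout

| module | role |
|---|---|
| `relhom.datasets` | FASTA/manifest IO, family hierarchy, leave-one-family-out splits, balanced negative resampling, identity filtering |
| `relhom.profile_hmm` | profile HMM built from the positive-training MSA; Viterbi decoding maps query residues to alignment columns |
| `relhom.logic_repr` | ground-atom emitters: sequence composition (`Seq`), conserved columns (`Aln_cons`), conserved physico-chemical columns (`Aln_pc`) |
| `relhom.pattern_miner` | APRIORI-style level-wise mining of frequent conjunctive patterns with anti-monotone pruning |
| `relhom.propositional` | rule → binary-feature propositionalization, chi-square feature selection, SVM/decision-tree training and scoring |
| `relhom.evaluation` | per-family T-run evaluation, rank-based AUC, Wilcoxon rank-sum comparison, AUC-vs-families curves |
| `relhom.synthetic_data` | synthetic superfamily benchmarks with planted conserved columns and identity calibration |
| `relhom.cli` | `relhom simulate | extract | mine | train-eval | compare` |

## CLI quick start

```sh
cat > config.yaml <<'YAML'
seed: 7
representations: [Seq, Aln_cons, Aln_pc]
classifier: SVM-RBF          # or DecisionTree
max_length: 2
# min_confidence: {Seq: 0.25, Aln_cons: 0.25, Aln_pc: 0.5}   # defaults
# chi_square_delta: 0.05
simulate:
  n_families: 2
  seqs_per_family: 6
  length: 60
  n_conserved_columns: 6
  substitution_rate: 0.8
  n_decoy_families: 5
  decoy_seqs_per_family: 6
YAML

relhom simulate  --config config.yaml --out bench/
relhom extract   --config config.yaml --fasta bench/sequences.fasta \
                 --alignment bench/superfamily_msa.afa --out kb.pl
relhom mine      --config config.yaml --kb kb.pl --out rules.pl
relhom train-eval --config config.yaml --fasta bench/sequences.fasta \
                 --manifest bench/manifest.tsv \
                 --alignment bench/superfamily_msa.afa --out results/
relhom compare   --a results_a/summary.json --b results_b/summary.json
```

All stage outputs are plain text (Prolog-like knowledge bases and rule
files, TSV matrices and results) and carry a config-hash/seed header, so
every stage is independently inspectable and reruns are byte-identical for
a fixed seed.

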