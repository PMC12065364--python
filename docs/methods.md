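# Methods

## Model

`lglink` predicts links in a sparse bipartite biological network (A-side
entities such as piRNAs, B-side entities such as diseases) by fusing two
scorers trained on the same known associations.

**Global scorer.** The heterogeneous graph combines three edge types in one
block adjacency `A_g = [[S_p, A_s], [A_s^T, S_d]]`, where `S_p` and `S_d`
are within-side similarity matrices (values in [0, 1], unit diagonal) and
`A_s` is the bipartite association block. Propagation uses the
self-loop-augmented symmetric normalisation
`P̂ = D̃^{-1/2}(I + A_g)D̃^{-1/2}`, whose spectrum lies in [-1, 1], so
stacked layers cannot blow up activations. Initial node features are
random-walk-with-restart (RWR) proximity profiles of each side's
similarity network, passed through one per-side dense encoder into a
common 128-dimensional embedding, then through L=2 ReLU GCN layers and a
400/200/100 dense head. A pair score is the inner product of the two
refined node embeddings, and the model regresses the whole m×n score
matrix against the variant target `A'` (α=1 on training positives, 0 on
unknown *and withheld* pairs) under squared Frobenius loss with L2 weight
decay μ. Withholding validation and independent positives from `A'` (and
from the graph itself, which is built only from training positives) keeps
model selection and testing leakage-free.

**Supplementation.** Because the known association block is sparse, it can
be enriched before graph construction: `n_base` base classifiers
(logistic regression, random forest, Gaussian naive Bayes, cycled over
independently resampled balanced negative sets) are trained to separate
known positives from sampled unknown pairs using the pair's concatenated
similarity-profile rows as features. Unknown pairs whose mean score passes
the rule (threshold 0.5 by default; top-k and keep-all modes exist) enter
`A_s` weighted by that mean score; known edges stay exact 1s. Setting
`n_base: 0` disables the mechanism.

**Local scorer.** Each candidate pair is encoded as the h-hop enclosing
subgraph of the original (unsupplemented, training-visible) bipartite
graph: BFS neighborhoods of both cores, induced association edges, and
the target edge removed after extraction so the model can never read the
link it is scoring. Hop distances are computed before target-edge removal
and are provably unaffected by it (any path through the target edge is
longer than the direct distance to the other core), which keeps labels
well defined for pairs connected only by the target edge. Node labels
encode type and hop (cores 0/1; hop-i nodes 2i / 2i+1) and are one-hot
encoded into 2h+2 bins as initial features. L=2 tanh message-passing
layers (separate self and neighbor transforms, width 32) are concatenated
per node; concat-pooling the two cores gives a 2·L·32 = 128-dimensional
pair feature, scored by an MLP with 128 hidden units and a linear output,
trained with MSE on 0/1 labels.

**Fusion.** `Y = δ·Y_global + (1−δ)·Y_local`. δ defaults to 0.5; with
`delta: auto` the value is chosen from {0, 0.1, …, 1} by validation AUC.

## Evaluation protocol

Known positives of each B-side entity are folded five ways in input order
(fold = position mod 5); one rng-chosen fold pooled over all diseases
forms the independent positives, the remaining positives are re-folded
five ways into train (4 folds) and validation (1 fold). Each positive set
is paired with an equal number of negatives sampled uniformly without
replacement from unknown pairs, disjoint across the three sets. Repeating
with fresh seeds realises the repeated random partitioning used for method
comparison; a two-sided Wilcoxon rank-sum helper compares per-repeat
metric vectors. Leave-one-disease-out CV withholds every association of
one disease, trains on the rest, and scores the held-out disease's
positives against an equal sample of its unknown pairs. Metrics: AUC and
AUPR on raw scores; F1/ACC/PRE/SPE/SEN threshold min-max-rescaled scores
at 0.5 (the thresholding rule is a package choice; rank metrics are
unaffected by it).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `h` | 2 | enclosing-subgraph neighbor order; 1 gives too little context, large h approaches the global view |
| `epochs_local`, `lr_local` | 20, 0.001 | local-module Adam budget; more epochs overfit small subgraph sets |
| `n_layers_local` | 2 | message-passing depth (local models are insensitive to this) |
| `epochs_global`, `lr_global` | 1000, 0.001 | full-batch Adam on the matrix fit; see numerical notes |
| `mu` | 1e-4 | L2 decay of the global objective (unitless); weak by design |
| `alpha` | 1.0 | regression target on training positives |
| `delta` | 0.5 / `auto` | convex fusion coefficient |
| `rwr_restart` | 0.9 | RWR restart probability; high values keep profiles local |
| `supplement.n_base` | 15 | base-predictor count (3 families × 5 resamples) |
| `supplement.threshold` | 0.5 | mean-score cutoff for pseudo-edges |

Alignment scoring for A-side sequence similarity defaults to match +2,
mismatch −1, linear gap −1 (configurable); similarity is the alignment
score normalised by the geometric mean of self-scores, which guarantees
values in [0, 1] with unit diagonal. `N` mismatches everything, including
itself. B-side semantic similarity (e.g. ontology-derived) is consumed as
a precomputed matrix — deriving it from an ontology DAG is out of scope.

## Numerical choices

- **No autodiff dependency.** Both networks are small dense-matrix models;
  gradients are derived by hand and verified against finite differences
  in the test suite (max relative error ~1e-9).
- **Global training budget.** The variant-MSE fit passes through a long
  plateau (near-constant scores) before the inner-product factorisation
  breaks symmetry; on the supplemented graph this takes several hundred
  epochs. The default is therefore a fixed 1000-epoch budget (about 10 s
  at fixture scale), chosen where validation AUC plateaus across seeds;
  plateau-based early stopping is available (`patience`) but off by
  default because any short patience truncates some seeds mid-plateau.
- **Determinism.** All randomness flows through seeded numpy Generators
  (base seed + stage/repeat offsets, documented in the run manifest);
  two runs with identical config and seed produce byte-identical reports.
- **Degenerate inputs.** Isolated entities in RWR get uniform transition
  rows (with a warning); a pair whose subgraph is two isolated cores is
  still scored from the labeled, disconnected cores; zero-variance score
  vectors rescale to 0.5 before thresholding; ties in written score files
  break lexicographically by pair identifier.
- **Label encoding.** Labels beyond 2h+1 (possible only for nodes reached
  through the other core's neighborhood) clamp into the last one-hot bin.

## Synthetic data

The generator plants k blocks on both sides: associations are Bernoulli
(p_in = 0.30 within blocks, p_out = 0.02 across; defaults m=150, n=20,
k=3 mimic the many-A-few-B shape of curated ncRNA–disease data), and both
similarity matrices mix the block indicator (weight `sim_signal` = 0.6)
with uniform noise plus Gaussian jitter (sd 0.05). This captures the
method's core premise — association patterns recoverable from graph
proximity plus similarity — and provides a difficulty dial. It does *not*
emulate real-data properties such as heavy-tailed degree distributions,
per-disease cohort biases, sequence-level signal, or ontology structure,
so passing tests demonstrate correct mechanics and signal recovery under
block structure, not performance on any real association database.

## Known limitations

- Dense matrix implementations throughout: appropriate up to a few
  thousand nodes, not for 10^4+ entity catalogs without sparsification.
- No subgraph-size cap for hub nodes; extraction cost grows with hub
  degree.
- The base-predictor supplementation ensemble is a configurable structural
  re-implementation (families, resampling, threshold are explicit
  choices), not a reproduction of any specific published predictor bank.
- Thresholded metrics depend on the min-max rescaling rule; compare
  methods on AUC/AUPR when score calibration differs.
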