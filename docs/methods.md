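# Methods

## Problem setting

`treepairs` infers missing entries of a partially known interaction
network from per-node measurements.  The network is an adjacency matrix
*Y* over one node set (homogeneous, symmetric: protein–protein or genetic
interactions, metabolic couplings) or two node sets (bipartite:
transcription factors × genes, drugs × proteins).  Every node *n* carries
a numeric feature vector *x(n)* — expression profiles, phylogenetic
profiles, chemical substructures, domain annotations — and each known
entry *y*<sub>ij</sub> ∈ {0, 1} states whether nodes *i* and *j* interact.
Inference is cast as supervised binary classification on node pairs: the
learning sample LS<sub>p</sub> collects all pairs with a known label, a
class-probability model *f*<sup>p</sup> is trained on it, and the unknown
entries are ranked by predicted probability.

Unknown entries are excluded from LS<sub>p</sub> at load time; deciding
whether unlabeled pairs count as negatives is a protocol-level choice made
where datasets are constructed (the synthetic generator produces fully
labeled networks, so the question does not arise there).  Self-interactions
are never enumerated or predicted on homogeneous networks.

## Base learner

Both approaches use ensembles of extremely randomized trees: at each tree
node, K candidate splits are drawn (a random feature with a random
cut-point each) and the best by Gini impurity is kept.  Defaults follow
the method's standard setting: 100 trees, K = round(√p) where p is the
number of candidate attributes the model actually sees (the concatenated
dimension for the global approach, a single side's dimension for local
models), no bootstrap resampling, fully grown trees.  Leaf probabilities
are raw class frequencies; optional Laplace smoothing
(n₁+α)/(n+2α) is exposed but off by default.  Bootstrap resampling is
exposed for the all-binary-features situation, where random cut-points
alone cannot diversify the ensemble.  The ensemble itself is scikit-learn's
`ExtraTreesClassifier`, wrapped to enforce these conventions; degenerate
single-class training sets yield constant models at the observed
prevalence rather than errors.  Trees extend to vector outputs (split
scores average the impurity reduction over outputs), which the local
multi-output variant uses.

## Global approach

One ensemble is trained on concatenated pair vectors *x(n_r) | x(n_c)*.
On homogeneous networks each training pair is presented in both orderings,
and predictions are symmetrized by combining the probabilities of the two
orderings.  The combination is the arithmetic mean — consistent with the
averaging used everywhere else in the framework, and it makes predictions
exactly swap-invariant; a max-combination is available as an option.
Pair enumeration is row-major over the adjacency so seeded runs are
bit-reproducible.

Each leaf of a global tree collects training pairs forming a rectangular
submatrix of *Y* that the tree drives toward all-connected or
all-disconnected — a feature-directed bicluster.  `biclusters()` reports,
per leaf, the member nodes, edge count, edge purity and the root-to-leaf
conjunction of feature tests.

## Local approach

Single-output: for every column node seen in LS<sub>p</sub>, a model over
row features is trained on that node's labeled pairs (symmetrically per
row node; one family of per-node models on homogeneous networks).  A pair
of two seen nodes is scored by the arithmetic mean of its two per-node
probabilities; a pair with one unseen node by the seen node's model alone.

Multi-output: two ensembles only — row features → interaction profile over
the seen columns, and column features → profile over the seen rows.  This
requires the seen×seen adjacency block to be fully observed (multi-output
trees cannot handle missing outputs); a partially observed block raises an
error directing the user to the single-output variant, and seen×seen pairs
cannot be scored out-of-sample by this variant at all.  On homogeneous
networks a single profile model is trained with diagonal outputs fixed at
0: the diagonal is never labeled, and absence of self-interaction is the
convention used throughout.

### Two-step procedure for pairs of two unseen nodes

Neither local variant can directly score a pair whose two nodes are both
absent from LS<sub>p</sub>.  The two-step procedure first scores the
unseen-row × seen-column block with the first-step column-side models (and
the seen-row × unseen-column block with the row-side models), binarizes
each block, then trains per-unseen-row models from seen-column features to
the binarized labels (symmetrically per unseen column; one joint
multi-output model per side in the multi-output variant, for four
ensembles in total).  A TSxTS pair is scored by the mean of its two
second-step predictions.

Binarization threshold: the predicted edge proportion in each block is
matched to the edge prevalence of the training sample of pairs
(positives/(positives+negatives) over the pairs actually trained on).
Concretely, m = floor(t·N) scores are marked positive: all scores strictly
above the cutoff (the (m+1)-th largest score), then scores tied at the
cutoff admitted in ascending (row index, column index) order until m is
reached.  The deterministic tie-break is this package's choice — only the
proportion itself is prescribed by the method — and makes binarization
reproducible; it guarantees m/N ≤ t < (m+ties)/N.  Step-1 labels are
recomputed per CV fold, never cached.  Second-step models reuse the
first-step hyper-parameters.

## Evaluation protocol

Test pairs fall into four families by whether each node occurs in some
training pair: LSxLS, LSxTS, TSxLS, TSxTS (the middle two merge on
homogeneous networks).  Two CV schemes cover them:

* **CV on pairs** — known pairs are randomly partitioned into folds;
  evaluates LSxLS generalization.
* **CV on nodes** — the row and column node sets are independently
  partitioned into folds; fold i holds out row-group i and column-group i
  jointly (fold geometry pairs row-fold i with column-fold i, giving
  `folds` iterations per run rather than all crossings).  Training uses
  the known pairs inside the seen×seen block; the held-out blocks supply
  the three (two, homogeneous) test families.

AUROC is the Mann–Whitney statistic (half credit for ties, so a constant
ranking scores exactly 0.5).  AUPR is step-wise average precision with no
interpolation — appropriate for the heavily skewed label distributions of
interaction networks, where a constant ranking scores exactly the edge
prevalence.  Metrics are computed per fold, then averaged over folds and
runs; pooled score curves are kept for plotting only.  Folds whose test
labels are single-class are skipped with a warning and recorded.  A 5-fold
option is exposed for large networks.

Baselines: node degree is itself predictive in biological networks
(hubs keep acquiring edges), so pairs are also ranked by the sum of the
two training degrees (LSxLS) or the seen node's training degree
(LSxTS/TSxLS); TSxTS pairs carry no degree information and fall back to
the random baseline (constant scores).

During CV on pairs a test pair can involve a node whose every pair fell
into the test fold; the local single-output adapter then falls back to the
one available per-node model, or to the training prevalence when both
nodes are unseen.  This keeps the protocol total; such pairs are rare at
realistic densities.

## Synthetic networks

The generator draws a latent stochastic block model.  Each node receives a
latent group; the edge probability of a pair is the (row-group,
column-group) entry of a block-density matrix, optionally multiplied by
heavy-tailed per-node weights exp(s·z), z ∼ N(0,1) (degree skew, producing
hubs) and clipped to [0, 1]; labels can additionally be flipped with a
fixed probability.  A `signal_fraction` of the feature columns are noisy
group indicators (the first k cover every group once, so the group is
always recoverable); the rest are standard normal noise.  This emulates
the structure the methods exploit in real data — correlated blocks of
informative measurements plus many irrelevant ones, checkerboard adjacency
structure, sparse edges, hub-dominated degrees — while admitting a
noiseless regime (block probabilities in {0, 1}, zero feature noise,
exactly balanced groups) where the adjacency is a deterministic function
of the observable features and exact-recovery tests are possible.

What the generator does **not** emulate: the biological semantics of real
feature sets, transitivity/motif structure beyond blocks, correlated
missingness, and positive-unlabeled ambiguity (labels are exact unless
flipped).  Passing tests therefore demonstrate that the algorithms recover
feature-linked block structure and node-degree effects under the stated
noise — not performance on any particular real network.

### Default study conditions

* Bipartite fixture: 200×150 nodes, 100 features per side
  (`signal_fraction` 0.2, noise sd 0.3), 4×3 latent groups with a
  diagonal-dominant block matrix whose mean density is 0.02 (high blocks
  ≈ 0.056, low 0.002), degree skew 0.75.  The density matches the sparse
  regime of curated interaction datasets (0.005–0.03); the skew makes
  node-specific connectivity learnable only from observed edges, which is
  what separates the four families in difficulty and gives the degree
  baseline genuine signal to beat.
* Homogeneous fixture: 200 nodes, symmetric 4×4 blocks at mean density
  0.03, otherwise identical.
* Noiseless fixture: 120×90 nodes, 3 groups with identity block matrix,
  zero noise, balanced groups (40/40/40 and 30/30/30), 40 features per
  side.  Balanced groups with balanced holdouts make every block's true
  edge fraction exactly 1/3 = the training prevalence, so proportion-
  matched binarization can recover the hidden labels exactly.

### Benchmark problem sizes

The reference benchmark (`treepairs.benchmarks.ordering_benchmark`) runs
10 runs of 5-fold CV under both schemes for the global, local
single-output and multi-output methods and the degree baseline on the
bipartite fixture, scoring with 20-tree ensembles; the full benchmark
completes in minutes on one CPU.  The tree count trades a little
per-fold variance for tractability of the ~36 000 ensembles the local
single-output protocol trains; means over 50 fold×run combinations are
stable.  The noiseless-recovery experiment uses 50 trees.  The package
default (`LearnerParams`) remains 100 trees.

## Numerical conventions

* All randomness flows from one experiment seed through
  `SeedSequence`-based child seeds keyed by run / fold / model, so any
  fold is re-runnable in isolation; seeds stay below 2³¹.
* K = round(√p) (round, not floor), floored at 1.
* Probability averaging is plain arithmetic mean everywhere (tree leaves,
  the two orderings of a homogeneous pair, the two per-node or two
  second-step predictions).
* Degenerate inputs: single-class training labels give constant models;
  single-class test folds are skipped and counted; empty unseen-node sets
  give empty second-step model sets; `target_proportion` 0 and 1 binarize
  to all-negative and all-positive.

## Known limitations

* The local single-output variant trains one ensemble per seen node and
  dominates runtime on dense CV protocols.
* Multi-output models require a fully observed seen×seen block and cannot
  score seen×seen pairs out of sample.
* No positive-unlabeled handling: unlabeled entries are either excluded
  (default) or treated as negatives by the caller's dataset construction.
* Feature importances are impurity-based and inherit their known bias
  toward high-cardinality features; features arrive precomputed and no
  normalization is applied.
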