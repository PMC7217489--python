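# Methods

This note records the models, the numerical choices, and the reasoning
behind the defaults, in enough detail to re-derive or challenge any of
them.

## The two-stage code-length model

Every description length is measured in bits (log base 2). A single
feature (gene) observed in a cluster of `n` cells is coded in two stages:

1. **Zero indicator.** Which entries are zero, under a Bernoulli model
   with Laplace-smoothed probability `p_zero = (z + 1)/(n + 2)` (`z` =
   number of zeros). Smoothing keeps all-zero and all-nonzero clusters
   finitely codable.
2. **Continuous stage.** The nonzero values, transformed to
   `y = log2(x + 1)`, under a Gaussian `N(μ̂, σ̂²)` fitted on the same
   values by maximum likelihood. Per value the cost is
   `½·log2(2πσ̂²) + (y − μ̂)²/(2σ̂²·ln 2)`.

Both stages are fitted in one pass, O(n) per feature, and evaluated
column-vectorized over whole matrices. Fitting on raw counts instead of
`log2(x+1)` would make the Gaussian badly misspecified for overdispersed
counts; the transform is the standard variance-stabilizing choice.

**Parameter charge.** A self-coded cluster pays `(p/2)·log2 n` bits per
feature model (`p` = 1 for a zero-only model, 3 otherwise) — the two-part
MDL asymptotic charge. A partition additionally pays the label bits
`n·H(cluster proportions) + c·log2 n`. These two charges are what stops
the merge sweep from splitting noise: measured on homogeneous simulated
clusters, dividing always *lengthens* the description.

**Degeneracy floors.** The fitted variance is floored at **0.1** on the
`log2(x+1)` scale. The floor is set by the resolution of the data: counts
are integers, so two distinguishable values differ by roughly 0.1–0.5
log2 units over the typical expression range, and a model should not claim
precision beyond that. A much smaller floor lets a model fitted on one or
two nonzero values assign thousands of bits to a value a fraction of a
count away, letting a single near-constant gene overrule every other gene
in a similarity comparison (we observed exactly this on a 12-cell
example before fixing the floor).

**Sign.** The continuous stage is a differential (density-based) code, so
code lengths can be negative for tightly concentrated values. The merge
criterion uses `|L_m|` and is well defined for either sign; no
discretization constant is added.

## The merge sweep

The initial partition divides the (optimally ordered) HAC tree into
sub-clusters of at most `t − 1` cells, contiguous in the leaf order
(`balanced` mode recurses into both children of every oversized node;
`skewed` mode first detaches the minimal subtree holding ≥ t leaves, which
isolates a small tight group hanging off a large node instead of splitting
it across its sibling). Head and tail sub-clusters are accumulated to
≥ t cells. Each middle sub-cluster below t cells is compared by cross
code length — the bits to encode it under per-gene models fitted on the
candidate neighbor — against the growing left cluster versus the
*right-minimax* union (the smallest union of following sub-clusters with
≥ t cells; comparing against a single, possibly tiny right neighbor would
be noise-dominated). Ties go left. Once the inspected cluster holds
≥ t cells, the two-part test runs:

```
L_m = L(left ∪ inspected as one cluster)
L_d = L(left, inspected as two clusters, labels included)
merge  ⇔  L_d − L_m ≥ −r·|L_m|
```

After a split the just-inspected cluster becomes the new left cluster.
The tail receives the same test against the final left cluster — without
it, two halves of one true population separated by the tail boundary could
never merge. If the tail never reached t cells (possible only when the
middle is exhausted), it is folded into the last cluster so the ≥ t
guarantee holds whenever `n ≥ 2t`; when `n < 2t` the single-cluster
partition is returned with a warning.

### Defaults and why

- `metric="cosine"`, `linkage="complete"`: cosine is computed purely with
  dense/sparse linear-algebra products (fast, BLAS-backed); complete
  linkage gives compact blocks that divide cleanly.
- `t = max(5, ⌈0.01·n⌉)`: the minimum cluster size a user would call a
  cluster rather than an outlier group; 1% of cells, floored at 5.
- `r_minmdl = 0`: the pure MDL rule — split exactly when dividing
  shortens the total description. A positive `r` demands that a split save
  `r·|L_m|` bits, but `|L_m|` grows with the *left* cluster while the
  inspected cluster stays near `t` cells, so the relative saving of a true
  boundary shrinks like `t/|left|`: with `r = 0.1` on the 8-population
  benchmark every boundary is suppressed and everything merges into one
  cluster. Measured on strongly separated simulations the normalized
  saving `(L_d − L_m)/|L_m|` is always positive within populations
  (≥ +0.006; the parameter and label charges regularize) and always
  negative across true boundaries (−0.004 to −0.08), so `r = 0`
  discriminates cleanly. `r` remains exposed as a deliberate merge bias
  for users who want coarser clusterings.
- `optimal_ordering=True` with `ordering_threshold=10_000`: the ordering
  DP is O(n³) and worthwhile below ~10⁴ cells; above that a plain
  dendrogram order is used (community extension is the better tool there).

### Optimal leaf ordering

The Bar-Joseph dynamic program is implemented in-package: for each
subtree, a table of the best achievable cost of an ordering starting at
leaf i and ending at leaf j (necessarily in opposite children), combined
through two min-plus matrix products over the cross-child distance block;
backtracking re-derives the argmin pairs. It is exact — verified against
exhaustive enumeration of all `2^(n−1)` flip orderings — and runs in ~4 s
at n = 1000. scipy's `optimal_leaf_ordering` was evaluated for this role
and rejected: in the installed version it returns orderings that
exhaustive enumeration beats on about half of random small instances, so
it cannot back an optimality contract. An ordering and its reversal are
equivalent; the direction with the smaller first leaf index is chosen so
results are invariant to row permutations of the input.

### Community extension

For large datasets, Leiden communities on the (mutual or union) KNN graph
replace per-cell sub-clusters: an HAC tree over community centroids fixes
the community order, and the same merge engine runs with code lengths
computed on the pooled member rows, so the final clusters are unions of
communities. The Leiden resolution is binary-searched upward until at
least `min_communities` communities exist (default `⌈n/1000⌉` clamped to
[20, 500]; the method needs "many small communities" for the merge step to
have anything to decide). If the search cannot reach the floor, the run
proceeds with a warning rather than failing.

## KNN tools

**Imputation** (per iteration): recompute distances on the current matrix
(imputed values should attract similar cells; disable with
`recompute_distances=False` for speed), find each cell's k neighbors, and
for each zero entry whose expressing-neighbor fraction meets the
iteration's threshold, substitute the mean (or median) of the neighbors'
*nonzero* values. Default schedule `(1.0, 0.9, 0.8)`: entries expressed in
all neighbors first, then in most. Nonzero entries are never touched, and
an imputed value always lies within the range of the contributing neighbor
values.

**Rare-profile detection** (per iteration): each remaining cell's mean
distance to its k nearest neighbors among remaining cells; cells above
`d_cutoff` are marked rare and leave the pool. The automatic cutoff is the
Tukey upper fence `Q3 + 1.5·IQR` of the first iteration's distribution —
scale-free and transparent; it is frozen after iteration 1 so later
iterations only surface cells that were shielded by already-removed
neighbors. The mean (not the maximum) of the k distances is used for
robustness to a single aberrant neighbor. Detection is flagging for
inspection, not removal: the API returns labels, never a filtered matrix.
In the benchmarks, detection runs on `log2(count+1)` values — on raw
counts the mean-kNN-distance distribution of normal cells is heavy-tailed
(low-depth cells have unstable directions), which costs sensitivity and
inflates false positives.

**Imputation benchmark**: detection is scored as binary classification of
the observed zeros (dropout vs true zero) by the expressing-neighbor
fraction, summarized by ROC/AUC; smoothing by the MSE over true-dropout
entries and its ratio to the MSE of leaving the zeros in place.

## Marker-gene ranking

Per bootstrap round: shuffle the gene column order (a pure order
permutation — importance must not depend on column position), stratified
K-fold split, and within each fold bootstrap-resample the *training* cells
only (resampling before the split would leak duplicated cells into the
validation fold; we measured 0.76 "accuracy" on pure noise with that
mistake). One XGBoost classifier per fold, early-stopped on the held-out
fold; split counts are taken from the model truncated at the best
iteration — trees grown during the patience window are discarded by
prediction and must not contribute importance (leaving them in pushes
high-variance genes above the noise band even under shuffled labels).
Counts are summed across folds, mapped back through the permutation, and
aggregated as mean ± sd over rounds. Defaults: 30 rounds, 5 folds,
`max_depth=4`, `learning_rate=0.3`, up to 100 trees with patience 10. The
held-out accuracy is reported next to the table so a no-signal comparison
is visible; it carries a mild optimistic bias from early-stopping
selection on the same fold.

## Agreement metrics

CCR pools all within-cluster pairs of the candidate partition and reports
the fraction also co-clustered in the reference; `per_cluster=True`
averages per-cluster ratios instead. An all-singleton candidate has no
pairs and scores 1.0 vacuously (reported with `n_pairs_evaluated = 0`).
Any refinement of the reference scores exactly 1.0 — the metric is built
not to penalize discovering sub-structure. Note that CCR is *not*
monotone under refinement of the candidate in general: refining removes
evaluated pairs, and removing hit pairs can lower the pooled ratio (e.g.
reference {a,b},{c}: candidate {a,b,c} scores 1/3, its refinement
{a,c},{b} scores 0). ARI is the Hubert–Arabie chance-corrected
pair-counting index, delegated to scikit-learn and cross-checked in the
tests against an independent brute-force pair scan.

## Synthetic benchmark generator

Per-gene base means are lognormal (`meanlog = 1`, `sdlog = 1`, i.e. median
~e ≈ 2.7 counts); each cluster multiplies a random `de_gene_fraction` of
genes by `2^lfc` with `lfc ~ N(0, de_logfc_scale)`; counts are negative
binomial with `var = μ + dispersion·μ²` (`dispersion = 0.2`, a typical
UMI-scale overdispersion); dropout zeroes each truly nonzero entry
independently with probability `dropout_rate` (default 0.05). Cluster
labels are i.i.d. categorical with proportions
⟨0.3, 0.2, 0.15, 0.15, 0.05, 0.05, 0.05, 0.05⟩. Outlier cells, when
requested, inflate a random gene subset by `outlier_scale`. An
expression-dependent dropout mode (logistic in `log2(count+1)`, rescaled
to the same expected rate) is available but off by default, because the
uniform mode keeps the realized rate analyzable in closed form.

Benchmark sizes used by the test suite: 1,000 cells × 500 genes for
clustering and imputation (20 seeds for clustering), 500 × 300 with 2%
outliers for rare detection (20 seeds), 10,000 × 1,000 for generator
calibration. "Strong separation" in the clustering and imputation
benchmarks is fixed as `de_gene_fraction = 0.3, de_logfc_scale = 3.0`:
adjacent populations then differ in roughly half their genes at typical
|log2 FC| ≈ 2.4.

What the generator does *not* emulate: library-size variation and
cell-level capture efficiency, batch effects, gene–gene correlation within
a population (genes are conditionally independent), trajectories, and
expression-dependent dropout (by default). Passing benchmarks on this
generator therefore demonstrates correctness of the machinery and
sensible behavior under the stated noise model — not performance on any
real dataset.

## Degenerate inputs and determinism

All-zero cells are maximally distant (1.0) under cosine/correlation;
neighbor ties break by ascending cell index (stable sorts); HAC follows
scipy's deterministic merge order, so results are reproducible on one
platform, and permutation invariance is guaranteed only for tie-free
distance matrices; every stochastic routine takes a seed and reruns are
byte-identical. Approximate-NN search is a pluggable backend (hnswlib if
installed, or any callable); when no backend is available the call fails
with an explicit instruction to use exact search — there is no silent
substitution — and ANN results always carry a recall estimate measured
against exact search on a subsample.

## Known limitations

- The merge sweep is greedy left-to-right over the leaf ordering; it does
  not revisit committed boundaries, so a poor ordering (e.g. with optimal
  ordering disabled on hard data) degrades results.
- Code lengths assume conditionally independent genes; strongly
  correlated gene modules are over-counted as evidence.
- The Gaussian stage on `log2(x+1)` is a pragmatic continuous model; for
  data far from NB-like counts (e.g. already-normalized expression) the
  zero-indicator stage carries little information.
- Imputation at very high dropout rates biases toward cluster means
  (over-smoothing); the MSE-ratio benchmark quantifies but does not
  remove this.
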