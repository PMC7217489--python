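# scmirac

Exploratory analysis tools for single-cell RNA-seq count matrices, built
around **MIRAC** — *minimum-description-length iteratively regularized
agglomerative clustering* — together with the k-nearest-neighbor methods
that accompany it in a typical workflow: gene-dropout imputation,
rare-transcriptomic-profile detection, boosted-tree ranking of
cluster-separating genes, cluster-agreement metrics (CCR, ARI), and a
negative-binomial benchmark simulator with known ground truth.

The intended user is someone exploring a cell × gene count matrix who wants
clusters that are robust to noise, a principled (not threshold-tuned) rule
for how far to split, and the surrounding utilities to stress-test the
result — all scriptable from Python.

## The method

Given an `n × m` count matrix `X` (cells × genes), MIRAC proceeds in three
steps:

1. **Order.** Build a hierarchical agglomerative clustering (HAC) tree on
   pairwise cell distances (cosine by default) and reorder its leaves with
   the Bar-Joseph dynamic program so that the sum of distances between
   adjacent leaves is minimal over all `2^(n−1)` flip-equivalent orderings.
2. **Divide.** Cut the tree into minimal sub-clusters of at most `t − 1`
   cells, each contiguous in the leaf ordering. Restricting candidate
   partitions to contiguous runs with all clusters ≥ `t` cells collapses
   the search space from the Bell number `B_n` to
   `C_n^{t..n} = Σ_{k=1}^{⌊n/t⌋} C(n−k(t−1)−1, k−1)` compositions
   (23 at `n = 60, t = 20`, versus `B_60 ≈ 10^59`).
3. **Merge.** Sweep the ordered sub-clusters left to right. A sub-cluster
   below `t` cells is absorbed toward whichever side it is more similar to,
   where similarity is the cross code length (bits to encode it under a
   model fitted on the neighbor — against the *right-minimax* union of
   following sub-clusters, for stability). Once the inspected cluster
   reaches `t` cells, compute the two-part description lengths
   `L_m` (left ∪ inspected as one cluster) and `L_d` (kept divided,
   including the bits to transmit the labels), and

   ```
   merge  ⇔  L_d − L_m ≥ −r·|L_m|
   ```

   with `r = 0` by default (the pure MDL rule: split exactly when dividing
   shortens the total description).

Each gene is coded in two stages — a Laplace-smoothed Bernoulli indicator
for which entries are zero, then a Gaussian code for `log2(count + 1)` of
the nonzero values — plus a `(p/2)·log2 n` parameter charge per fitted
model. This is what makes the split rule self-regularizing: splitting buys
tighter per-cluster fits but pays for an extra model per gene and for the
label bits.

The KNN tools share one assumption: a non-rare cell resembles at least `k`
other cells. Imputation fills a zero entry from the nonzero values its
neighbors carry for that gene (strictest agreement first, relaxed over
iterations); rare-profile detection iteratively marks cells whose mean
distance to their `k` nearest neighbors exceeds a Tukey-fence cutoff and
removes them from the pool. Cluster-separating genes are ranked by how
often a gradient-boosted tree classifier (XGBoost) splits on them,
aggregated over bootstrap rounds with shuffled gene order — a ranking for
inspection, deliberately not a p-value.

## Worked example

`examples/simulate_and_cluster.py` draws the standard 8-population
benchmark (population proportions ⟨0.3, 0.2, 0.15, 0.15, 0.05, 0.05, 0.05,
0.05⟩, ~5% gene dropout) and clusters it:

```
$ python examples/simulate_and_cluster.py
simulated 1000 cells x 500 genes, 19735 dropout events (5.0% of expressed entries)
MIRAC found 8 clusters, sizes [48, 48, 56, 60, 152, 163, 196, 277]
12 merge/split decisions were MDL-tested; 5 merged
agreement with truth: CCR=1.000  ARI=1.000 over 87581 co-clustered pairs
```

All 8 populations are recovered exactly: the cluster consistent ratio (CCR,
the fraction of co-clustered cell pairs that the reference also
co-clusters) and the adjusted Rand index are both 1. The other scripts in
`examples/` demonstrate dropout imputation (detection AUC 0.84, MSE ratio
0.89 on the same benchmark), rare-cell recovery (sensitivity 1.0 at 1.6%
false positives), marker ranking, community-extended clustering for larger
datasets, and the partition-count arithmetic.

A thin CLI mirrors the library one call per subcommand
(`scmirac simulate|cluster|cluster-community|impute|rare|markers|agreement|heatmap`);
results are identical to the corresponding library call.

## Layout

| module | contents |
| --- | --- |
| `scmirac.matrix_core` | `CountMatrix` container, lazy cached distances, exact/ANN k-NN, KNN graphs |
| `scmirac.mdl_coding` | two-stage code-length engine and merge-decision records |
| `scmirac.mirac` | HAC tree, optimal leaf ordering, tree division, MDL merge sweep, community extension, partition counts |
| `scmirac.knn_tools` | dropout imputation, rare-profile detection, imputation benchmark |
| `scmirac.marker_genes` | boosted-tree importance ranking and gene panels |
| `scmirac.metrics_eval` | CCR and ARI |
| `scmirac.synthetic_data` | negative-binomial benchmark simulator, worked fixture |
| `scmirac.cli_viz` / `scmirac.cli` | heatmap preparation, parallel map, CLI entry points |

See `docs/methods.md` for the model details, parameter defaults and their
rationale, and known limitations.
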