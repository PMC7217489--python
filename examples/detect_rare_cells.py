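"""Mark rare transcriptomic profiles: inject 2% strongly displaced cells
into a clustered simulation and recover them by iterative mean-kNN-distance
screening on log-transformed counts."""

import numpy as np

from scmirac import CountMatrix, RareDetectionParams, SimParams, detect_rare, simulate_counts

sim = simulate_counts(SimParams(n_cells=500, n_genes=300,
                                de_gene_fraction=0.3, de_logfc_scale=3.0,
                                outlier_cells=10, outlier_gene_fraction=0.2,
                                outlier_scale=20.0, seed=0))
logX = CountMatrix(np.log2(sim.observed.toarray() + 1.0))
labels, reports = detect_rare(logX, RareDetectionParams(k=10, d_cutoff="auto"))

truth = np.zeros(500, dtype=bool)
truth[sim.outlier_ids] = True
rare = labels == "rare"
print(f"injected outliers: {truth.sum()}; marked rare: {rare.sum()}")
print(f"sensitivity = {rare[truth].mean():.2f}, "
      f"false-positive rate = {rare[~truth].mean():.3f}")
for r in reports:
    print(f"  iteration {r['iteration']}: {r['n_remaining']} cells in pool, "
          f"cutoff {r['cutoff']:.3f}, marked {r['n_marked']}")
print("(the most distinct profiles fall in the earliest iterations)")
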