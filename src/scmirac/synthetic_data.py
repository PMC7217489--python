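"""Synthetic cluster-structured scRNA-seq count generator with known truth.

Counts are drawn from a negative-binomial model: per-gene base means are
lognormal, each cluster perturbs a random subset of genes by multiplicative
log2 fold changes, and gene dropout is simulated as independent Bernoulli
zeroing of truly nonzero entries.  The defaults mirror a standard
8-population benchmark design: cluster proportions
<0.3, 0.2, 0.15, 0.15, 0.05, 0.05, 0.05, 0.05> with a ~5% dropout rate.
Every run returns the true counts, the observed (dropout-corrupted)
counts, the dropout mask, and the true labels, so clustering, imputation
and rare-profile detection can all be scored without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_core import CountMatrix
from .mirac import Partition

DEFAULT_PROPORTIONS = (0.3, 0.2, 0.15, 0.15, 0.05, 0.05, 0.05, 0.05)

__all__ = ["SimParams", "SimOutput", "simulate_counts", "worked_fixture",
           "DEFAULT_PROPORTIONS"]


@dataclass
class SimParams:
    """Generator settings; defaults are the benchmark study conditions.

    ``de_gene_fraction`` of genes per cluster receive N(0, de_logfc_scale)
    log2 fold changes; ``dispersion`` is the NB inverse size (var = mu +
    dispersion * mu^2); ``dropout_rate`` is the expected fraction of truly
    nonzero entries zeroed.  ``dropout_mode="logistic"`` makes low-count
    entries drop more often while keeping the same expected rate.
    """

    n_cells: int = 2000
    n_genes: int = 1000
    cluster_proportions: tuple = DEFAULT_PROPORTIONS
    de_gene_fraction: float = 0.1
    de_logfc_scale: float = 1.0
    mean_log: float = 1.0
    sigma_log: float = 1.0
    dropout_rate: float = 0.05
    dropout_mode: str = "uniform"  # or "logistic"
    dispersion: float = 0.2
    outlier_cells: int = 0
    outlier_scale: float = 10.0
    outlier_gene_fraction: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        props = np.asarray(self.cluster_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        if not (0 <= self.dropout_rate <= 1):
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.dropout_mode not in ("uniform", "logistic"):
            raise ValueError("dropout_mode must be 'uniform' or 'logistic'")
        if props.min() * self.n_cells < 1:
            raise ValueError("smallest cluster proportion times n_cells is < 1 cell")
        self.cluster_proportions = tuple(props)


@dataclass
class SimOutput:
    truth: CountMatrix
    observed: CountMatrix
    dropout_mask: np.ndarray
    labels: Partition
    outlier_ids: np.ndarray
    cluster_means: np.ndarray = None


def simulate_counts(p: SimParams | None = None) -> SimOutput:
    """Draw one synthetic dataset; fully reproducible from ``p.seed``."""
    p = p or SimParams()
    rng = np.random.default_rng(p.seed)
    n, m = p.n_cells, p.n_genes
    n_clusters = len(p.cluster_proportions)

    labels = rng.choice(n_clusters, size=n, p=np.asarray(p.cluster_proportions))
    base_means = rng.lognormal(mean=p.mean_log, sigma=p.sigma_log, size=m)

    cluster_means = np.tile(base_means, (n_clusters, 1))
    n_de = int(round(p.de_gene_fraction * m))
    for kc in range(n_clusters):
        de_idx = rng.choice(m, size=n_de, replace=False)
        lfc = rng.normal(0.0, p.de_logfc_scale, size=n_de)
        cluster_means[kc, de_idx] *= 2.0 ** lfc

    mu = cluster_means[labels]  # n x m
    if p.dispersion > 0:
        size = 1.0 / p.dispersion
        p_nb = size / (size + mu)
        truth = rng.negative_binomial(size, p_nb)
    else:
        truth = rng.poisson(mu)
    truth = truth.astype(np.float64)

    # outliers: displace whole cells by inflating a random gene subset
    if p.outlier_cells > 0:
        outlier_ids = rng.choice(n, size=p.outlier_cells, replace=False)
        n_out_genes = max(1, int(round(p.outlier_gene_fraction * m)))
        for c in outlier_ids:
            genes = rng.choice(m, size=n_out_genes, replace=False)
            truth[c, genes] = np.round(truth[c, genes] * p.outlier_scale + p.outlier_scale)
    else:
        outlier_ids = np.array([], dtype=np.int64)

    nonzero = truth > 0
    if p.dropout_rate > 0:
        if p.dropout_mode == "uniform":
            prob = np.full(truth.shape, p.dropout_rate)
        else:
            # lower counts drop more; rescaled so the expected realized
            # fraction over nonzero entries equals dropout_rate
            w = 1.0 / (1.0 + np.log2(truth + 1.0))
            mean_w = w[nonzero].mean() if nonzero.any() else 1.0
            prob = np.clip(w * (p.dropout_rate / mean_w), 0.0, 1.0)
        dropout_mask = nonzero & (rng.random(truth.shape) < prob)
    else:
        dropout_mask = np.zeros(truth.shape, dtype=bool)

    observed = truth.copy()
    observed[dropout_mask] = 0.0

    cell_ids = [f"cell_{i}" for i in range(n)]
    gene_ids = [f"gene_{j}" for j in range(m)]
    return SimOutput(
        truth=CountMatrix(truth, cell_ids, gene_ids),
        observed=CountMatrix(observed, cell_ids, gene_ids),
        dropout_mask=dropout_mask,
        labels=Partition(labels=labels, role="reference"),
        outlier_ids=outlier_ids,
        cluster_means=cluster_means,
    )


_FIXTURE_TRUTH = np.array([
    # genes:  g0   g1   g2   g3  g4  g5     (cells 0-5: type A, 6-11: type B)
    [12, 9, 14, 0, 0, 1],
    [10, 11, 12, 0, 1, 0],
    [13, 8, 15, 1, 0, 0],
    [11, 10, 13, 0, 0, 0],
    [12, 12, 11, 0, 1, 1],
    [9, 10, 14, 1, 0, 0],
    [0, 1, 0, 11, 13, 10],
    [1, 0, 0, 12, 11, 12],
    [0, 0, 1, 10, 14, 9],
    [0, 1, 1, 13, 12, 11],
    [1, 0, 0, 11, 10, 13],
    [0, 0, 0, 12, 13, 10],
], dtype=float)

# two dropout events, both on truly expressed entries
_FIXTURE_DROPOUTS = [(0, 1), (7, 3)]


def worked_fixture() -> SimOutput:
    """Tiny deterministic 12-cell x 6-gene fixture with two hand-placed dropouts.

    Cells 0-5 express genes 0-2 (type A), cells 6-11 express genes 3-5
    (type B); used throughout the docs and unit tests because every
    expectation can be checked by hand.
    """
    truth = _FIXTURE_TRUTH.copy()
    mask = np.zeros(truth.shape, dtype=bool)
    for c, g in _FIXTURE_DROPOUTS:
        assert truth[c, g] > 0
        mask[c, g] = True
    observed = truth.copy()
    observed[mask] = 0.0
    labels = np.array([0] * 6 + [1] * 6)
    cell_ids = [f"cell_{i}" for i in range(12)]
    gene_ids = [f"gene_{j}" for j in range(6)]
    return SimOutput(
        truth=CountMatrix(truth, cell_ids, gene_ids),
        observed=CountMatrix(observed, cell_ids, gene_ids),
        dropout_mask=mask,
        labels=Partition(labels=labels, role="reference"),
        outlier_ids=np.array([], dtype=np.int64),
    )
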