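"""KNN-based gene-dropout imputation and rare transcriptomic profile detection.

Both methods rest on one assumption: every non-rare cell resembles at least
k other cells in its transcriptomic profile.  Imputation fills a zero entry
from the nonzero values its neighbors carry for that gene, over several
iterations with a relaxing expressed-neighbor-fraction requirement (genes
expressed in all neighbors first, then in most).  Rare detection marks the
cells whose mean distance to their k nearest neighbors is anomalously
large, removes them from the neighbor pool, and repeats, so the most
distinct profiles are marked in earlier iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix_core import CountMatrix, array_distances, _exact_knn

__all__ = [
    "ImputationParams",
    "RareDetectionParams",
    "impute_dropouts",
    "detect_rare",
    "dropout_benchmark",
]


@dataclass
class ImputationParams:
    k: int = 10
    n_iter: int = 3
    min_expr_fraction_schedule: tuple = (1.0, 0.9, 0.8)
    statistic: str = "mean"
    metric: str = "cosine"
    recompute_distances: bool = True
    seed: int | None = None

    def __post_init__(self):
        sched = tuple(self.min_expr_fraction_schedule)
        if len(sched) != self.n_iter:
            raise ValueError("schedule length must equal n_iter")
        if any(not (0 < f <= 1) for f in sched):
            raise ValueError("schedule fractions must be in (0, 1]")
        if any(a < b for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule fractions must be nonincreasing")
        if self.statistic not in ("mean", "median"):
            raise ValueError("statistic must be 'mean' or 'median'")
        self.min_expr_fraction_schedule = sched


@dataclass
class RareDetectionParams:
    k: int = 10
    d_cutoff: float | str = "auto"
    n_iter: int = 5
    metric: str = "cosine"

    def __post_init__(self):
        if self.k < 1 or self.n_iter < 1:
            raise ValueError("k and n_iter must be >= 1")


def impute_dropouts(X, p: ImputationParams | None = None):
    """Impute zero entries from k-nearest-neighbor expression.

    Per iteration, a zero entry (cell c, gene g) is replaced by the
    mean/median of the *nonzero* values of g among c's k neighbors whenever
    the fraction of neighbors expressing g reaches the iteration's schedule
    threshold.  Nonzero entries are never modified; the returned mask marks
    every imputed entry.
    """
    p = p or ImputationParams()
    ids = (X.cell_ids, X.gene_ids) if isinstance(X, CountMatrix) else (None, None)
    cur = X.toarray().copy() if hasattr(X, "toarray") else np.array(X, dtype=np.float64)
    n, m = cur.shape
    if p.k > n - 1:
        raise ValueError(f"k={p.k} must be <= n-1={n - 1}")
    mask = np.zeros((n, m), dtype=bool)
    idx = None
    for it in range(p.n_iter):
        if idx is None or p.recompute_distances:
            d = array_distances(cur, p.metric)
            idx, _ = _exact_knn(d, p.k)
        nz = cur != 0
        counts = np.zeros((n, m), dtype=np.int64)
        sums = np.zeros((n, m), dtype=np.float64)
        for j in range(p.k):
            nb = idx[:, j]
            counts += nz[nb]
            sums += cur[nb]
        frac = counts / p.k
        cand = (cur == 0) & (frac >= p.min_expr_fraction_schedule[it]) & (counts > 0)
        if not cand.any():
            continue
        if p.statistic == "mean":
            with np.errstate(invalid="ignore"):
                vals = sums / np.maximum(counts, 1)
            cur[cand] = vals[cand]
        else:
            rows, cols = np.nonzero(cand)
            for c, g in zip(rows, cols):
                nb_vals = cur[idx[c], g]
                cur[c, g] = float(np.median(nb_vals[nb_vals != 0]))
        mask |= cand
    out = CountMatrix(cur, cell_ids=ids[0], gene_ids=ids[1])
    return out, mask


def detect_rare(X, p: RareDetectionParams | None = None):
    """Mark cells whose mean k-NN distance exceeds a cutoff, iteratively.

    ``d_cutoff="auto"`` uses the Tukey upper fence (Q3 + 1.5 IQR) of the
    first iteration's mean-kNN-distance distribution.  Marked cells leave
    the neighbor pool, so moderately distinct profiles can surface in later
    iterations.  Returns ``(labels, reports)`` with labels in
    {"common", "rare"} and one report dict per iteration.
    """
    p = p or RareDetectionParams()
    d = array_distances(X.values if isinstance(X, CountMatrix) else np.asarray(X, float),
                        p.metric)
    n = d.shape[0]
    remaining = np.arange(n)
    rare = np.zeros(n, dtype=bool)
    cutoff = None if p.d_cutoff == "auto" else float(p.d_cutoff)
    reports = []
    for it in range(p.n_iter):
        if len(remaining) < p.k + 1:
            warnings.warn(f"fewer than k+1={p.k + 1} cells remain; stopping")
            break
        sub = d[np.ix_(remaining, remaining)]
        part = np.partition(sub, kth=p.k, axis=1)[:, 1: p.k + 1]
        mean_knn = part.mean(axis=1)
        if cutoff is None:
            q1, q3 = np.percentile(mean_knn, [25, 75])
            cutoff = float(q3 + 1.5 * (q3 - q1))
        marked = mean_knn > cutoff
        reports.append({
            "iteration": it + 1,
            "n_remaining": int(len(remaining)),
            "cutoff": cutoff,
            "n_marked": int(marked.sum()),
            "mean_knn_distance": mean_knn,
        })
        if not marked.any():
            break
        rare[remaining[marked]] = True
        remaining = remaining[~marked]
    labels = np.where(rare, "rare", "common")
    return labels, reports


def dropout_benchmark(truth, observed, dropout_mask, imputed, imputed_mask,
                      k: int = 10, metric: str = "cosine"):
    """Score dropout *detection* (ROC/AUC) and *smoothing* (MSE) on known truth.

    Detection treats every zero entry of ``observed`` as a binary
    classification case (dropout vs true zero) scored by the fraction of
    the cell's k neighbors expressing the gene.  MSEs are computed over the
    true-dropout entries; the reported ratio is mse_imputed / mse_observed.
    """
    from sklearn.metrics import roc_curve, auc as _auc

    T = truth.toarray() if hasattr(truth, "toarray") else np.asarray(truth, float)
    O = observed.toarray() if hasattr(observed, "toarray") else np.asarray(observed, float)
    I = imputed.toarray() if hasattr(imputed, "toarray") else np.asarray(imputed, float)
    dm = np.asarray(dropout_mask, dtype=bool)
    im = np.asarray(imputed_mask, dtype=bool)
    if not (T.shape == O.shape == I.shape == dm.shape == im.shape):
        raise ValueError("all matrices and masks must share one shape")
    if (O[dm] != 0).any():
        raise ValueError("dropout_mask must cover only zero entries of observed")
    if (T[dm] == 0).any():
        raise ValueError("dropout_mask must cover only nonzero entries of truth")

    d = array_distances(O, metric)
    idx, _ = _exact_knn(d, k)
    nz = O != 0
    counts = np.zeros(O.shape, dtype=np.int64)
    for j in range(k):
        counts += nz[idx[:, j]]
    score = counts / k

    zeros = O == 0
    y_true = dm[zeros].astype(int)
    y_score = score[zeros]
    fpr, tpr, _ = roc_curve(y_true, y_score)
    auc = float(_auc(fpr, tpr))

    mse_imputed = float(np.mean((I[dm] - T[dm]) ** 2)) if dm.any() else 0.0
    mse_observed = float(np.mean((O[dm] - T[dm]) ** 2)) if dm.any() else 0.0
    return {
        "roc_points": (fpr, tpr),
        "auc": auc,
        "mse_imputed": mse_imputed,
        "mse_observed": mse_observed,
        "mse_ratio": mse_imputed / mse_observed if mse_observed > 0 else float("nan"),
    }
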