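"""Count-matrix container with lazy, cached pairwise distances and k-NN queries.

Cells are always rows and genes columns; every reader normalizes orientation.
Pairwise distances are computed at most once per (matrix fingerprint, metric)
pair and cached on the container; any selection produces a new container with
a new fingerprint, so stale distances can never be reused.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

VALID_METRICS = ("cosine", "euclidean", "correlation")

__all__ = [
    "CountMatrix",
    "DistanceMatrix",
    "NeighborTable",
    "load_counts",
    "pairwise_distances",
    "knn_query",
    "knn_graph",
    "select",
]


class CountMatrix:
    """Cell x gene nonnegative expression matrix, sparse- or dense-backed.

    Parameters
    ----------
    values : array-like or sparse matrix, shape (n_cells, n_genes)
        Nonnegative, finite expression values.
    cell_ids, gene_ids : sequences of unique strings, optional
        Default to ``cell_0..`` / ``gene_0..``.
    """

    def __init__(self, values, cell_ids=None, gene_ids=None):
        if sp.issparse(values):
            self._values = values.tocsr().astype(np.float64)
            self.is_sparse = True
            data = self._values.data
        else:
            self._values = np.asarray(values, dtype=np.float64)
            if self._values.ndim != 2:
                raise ValueError("values must be 2-dimensional (cells x genes)")
            self.is_sparse = False
            data = self._values
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("expression values must be finite")
        if data.size and (np.min(data) if not self.is_sparse else data.min(initial=0.0)) < 0:
            raise ValueError("expression values must be nonnegative")
        n, m = self._values.shape
        self.cell_ids = self._check_ids(cell_ids, n, "cell")
        self.gene_ids = self._check_ids(gene_ids, m, "gene")
        self._cache: dict = {}
        # instrumentation: how many times each expensive quantity was computed
        self.compute_counts: dict = {}

    @staticmethod
    def _check_ids(ids, expected, what):
        if ids is None:
            return np.array([f"{what}_{i}" for i in range(expected)], dtype=object)
        ids = np.asarray(ids, dtype=object)
        if len(ids) != expected:
            raise ValueError(f"{what}_ids length {len(ids)} != {expected}")
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate {what} ids")
        return ids

    # -- basic protocol ----------------------------------------------------
    @property
    def values(self):
        return self._values

    @property
    def shape(self):
        return self._values.shape

    @property
    def n_cells(self):
        return self._values.shape[0]

    @property
    def n_genes(self):
        return self._values.shape[1]

    def toarray(self) -> np.ndarray:
        if self.is_sparse:
            return self._values.toarray()
        return self._values

    @property
    def source_hash(self) -> str:
        """Fingerprint of values + ids; cache keys are derived from it."""
        h = self._cache.get("_hash")
        if h is None:
            hasher = hashlib.sha1()
            if self.is_sparse:
                c = self._values.tocoo()
                hasher.update(c.row.tobytes())
                hasher.update(c.col.tobytes())
                hasher.update(c.data.tobytes())
            else:
                hasher.update(np.ascontiguousarray(self._values).tobytes())
            hasher.update("|".join(map(str, self.cell_ids)).encode())
            hasher.update("|".join(map(str, self.gene_ids)).encode())
            h = hasher.hexdigest()
            self._cache["_hash"] = h
        return h

    # -- lazy cached operations -------------------------------------------
    def pairwise_distances(self, metric: str = "cosine", workers: int = 1) -> "DistanceMatrix":
        """Lazy cached pairwise cell distances under ``metric``."""
        key = ("dist", metric)
        dm = self._cache.get(key)
        if dm is None or dm.source_hash != self.source_hash:
            self.compute_counts[key] = self.compute_counts.get(key, 0) + 1
            dm = _compute_distances(self, metric, workers)
            self._cache[key] = dm
        return dm

    def knn(self, k: int, metric: str = "cosine", method: str = "exact",
            ann_params: dict | None = None, ann_backend=None) -> "NeighborTable":
        key = ("knn", k, metric, method)
        nt = self._cache.get(key)
        if nt is None:
            self.compute_counts[key] = self.compute_counts.get(key, 0) + 1
            nt = knn_query(self, k, metric=metric, method=method,
                           ann_params=ann_params, ann_backend=ann_backend)
            self._cache[key] = nt
        return nt

    def select(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        return select(self, cell_mask, gene_mask)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise cell distances under a named metric."""

    metric: str
    values: np.ndarray
    source_hash: str = ""

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class NeighborTable:
    """Per-cell k nearest neighbors, rows ordered by nondecreasing distance."""

    k: int
    indices: np.ndarray
    distances: np.ndarray
    method: str = "exact"
    recall_estimate: float | None = None


# ---------------------------------------------------------------------------
# loading


def load_counts(path, fmt: str | None = None, genes_path=None, barcodes_path=None) -> CountMatrix:
    """Read a count matrix from ``.mtx`` (with gene/barcode sidecars) or dense TSV/CSV.

    MatrixMarket triplets follow the 10x convention (genes x cells) and are
    transposed to cells x genes.  Dense files carry cell ids in the first
    column and gene ids in the header row.
    """
    path = Path(path)
    if fmt is None:
        fmt = {"mtx": "mtx", "tsv": "tsv", "csv": "csv"}.get(path.suffix.lstrip("."), None)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name}; pass fmt=")
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "mtx":
        try:
            mat = mmread(str(path))
        except Exception as exc:  # scipy reports the offending line
            raise ValueError(f"malformed MatrixMarket file {path}: {exc}") from exc
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        barcodes_path = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        for p, what in ((genes_path, "genes"), (barcodes_path, "barcodes")):
            if not p.exists():
                raise FileNotFoundError(f"mtx format requires {what} sidecar: {p}")
        gene_ids = [ln.split("\t")[0] for ln in genes_path.read_text().splitlines() if ln]
        cell_ids = [ln.split("\t")[0] for ln in barcodes_path.read_text().splitlines() if ln]
        mat = sp.csr_matrix(mat).T  # genes x cells on disk -> cells x genes
        return CountMatrix(mat, cell_ids=cell_ids, gene_ids=gene_ids)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ValueError(f"malformed {fmt} file {path}: {exc}") from exc
        return CountMatrix(df.to_numpy(dtype=np.float64),
                           cell_ids=df.index.astype(str).to_numpy(dtype=object),
                           gene_ids=df.columns.astype(str).to_numpy(dtype=object))
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# distances


def array_distances(values, metric: str, workers: int = 1) -> np.ndarray:
    """Pairwise row distances of a raw (dense or sparse) array."""
    if metric not in VALID_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {VALID_METRICS}")
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows for pairwise distances")
    if metric == "euclidean":
        from sklearn.metrics import pairwise_distances as _skl_pd

        d = _skl_pd(values, metric="euclidean", n_jobs=workers if workers > 1 else None)
    elif metric == "cosine":
        d = _cosine_distances(values)
    else:  # correlation = cosine on row-centered values
        a = values.toarray() if sp.issparse(values) else np.asarray(values, dtype=np.float64)
        a = a - a.mean(axis=1, keepdims=True)
        d = _cosine_distances(a)
    d = np.asarray(d, dtype=np.float64)
    np.maximum(d, 0.0, out=d)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


def _compute_distances(X: CountMatrix, metric: str, workers: int = 1) -> DistanceMatrix:
    d = array_distances(X.values, metric, workers)
    return DistanceMatrix(metric=metric, values=d, source_hash=X.source_hash)


def _cosine_distances(values) -> np.ndarray:
    # 1 - (p.q)/(|p||q|) via matrix products; degenerate zero-norm rows are
    # maximally distant (distance 1) from everything else.
    if sp.issparse(values):
        norms = np.sqrt(np.asarray(values.multiply(values).sum(axis=1)).ravel())
        safe = np.where(norms > 0, norms, 1.0)
        unit = sp.diags(1.0 / safe) @ values
        sim = np.asarray((unit @ unit.T).todense())
    else:
        norms = np.linalg.norm(values, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        unit = values / safe[:, None]
        sim = unit @ unit.T
    np.clip(sim, -1.0, 1.0, out=sim)
    d = 1.0 - sim
    zero = norms == 0
    if zero.any():
        d[zero, :] = 1.0
        d[:, zero] = 1.0
    return d


def pairwise_distances(X: CountMatrix, metric: str = "cosine", workers: int = 1) -> DistanceMatrix:
    """Cached pairwise cell distances of ``X`` under ``metric``."""
    return X.pairwise_distances(metric=metric, workers=workers)


# ---------------------------------------------------------------------------
# k nearest neighbors


def _exact_knn(d: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = d.shape[0]
    # stable argsort breaks distance ties by ascending cell index
    order = np.argsort(d, axis=1, kind="stable")
    indices = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = order[i]
        indices[i] = row[row != i][:k]
    distances = np.take_along_axis(d, indices, axis=1)
    return indices, distances


def knn_query(X: CountMatrix, k: int, metric: str = "cosine", method: str = "exact",
              ann_params: dict | None = None, ann_backend=None) -> NeighborTable:
    """k nearest neighbors of every cell.

    ``method="exact"`` scans the cached distance matrix.  ``method="ann"``
    delegates to a pluggable approximate backend (``ann_backend(data, k,
    metric, params) -> (indices, distances)``, hnswlib by default) and also
    reports a recall estimate against exact search on a subsample.
    """
    n = X.n_cells
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= n-1, got k={k}, n={n}")
    if method == "exact":
        d = X.pairwise_distances(metric).values
        idx, dist = _exact_knn(d, k)
        return NeighborTable(k=k, indices=idx, distances=dist, method="exact")
    if method != "ann":
        raise ValueError(f"unknown knn method {method!r}")
    params = dict(ann_params or {})
    backend = ann_backend if ann_backend is not None else _hnsw_backend
    idx, dist = backend(X.toarray(), k, metric, params)
    idx = np.asarray(idx, dtype=np.int64)
    dist = np.asarray(dist, dtype=np.float64)
    # recall estimate on a subsample against the exact table
    sample = min(n, int(params.get("recall_sample", 50)))
    rng = np.random.default_rng(int(params.get("recall_seed", 0)))
    rows = rng.choice(n, size=sample, replace=False)
    exact_idx, _ = _exact_knn(X.pairwise_distances(metric).values, k)
    hits = sum(len(set(idx[i]) & set(exact_idx[i])) for i in rows)
    recall = hits / (sample * k)
    return NeighborTable(k=k, indices=idx, distances=dist, method="ann",
                         recall_estimate=recall)


def _hnsw_backend(data: np.ndarray, k: int, metric: str, params: dict):
    try:
        import hnswlib
    except ImportError as exc:
        raise RuntimeError(
            "approximate nearest-neighbor search requires the optional "
            "'hnswlib' backend, which is not installed; either install "
            "hnswlib, pass a custom ann_backend callable, or use "
            "method='exact'"
        ) from exc
    space = {"euclidean": "l2", "cosine": "cosine"}.get(metric)
    if space is None:
        raise ValueError(f"hnswlib backend does not support metric {metric!r}")
    n, dim = data.shape
    index = hnswlib.Index(space=space, dim=dim)
    index.init_index(max_elements=n, M=int(params.get("M", 16)),
                     ef_construction=int(params.get("ef_construction", 200)),
                     random_seed=int(params.get("seed", 0)))
    index.add_items(data, np.arange(n))
    index.set_ef(int(params.get("ef_search", max(2 * k, 64))))
    idx, dist = index.knn_query(data, k=k + 1)
    out_idx = np.empty((n, k), dtype=np.int64)
    out_dist = np.empty((n, k), dtype=np.float64)
    for i in range(n):
        keep = idx[i] != i
        out_idx[i] = idx[i][keep][:k]
        out_dist[i] = dist[i][keep][:k]
    if space == "l2":  # hnswlib reports squared euclidean
        out_dist = np.sqrt(out_dist)
    return out_idx, out_dist


def knn_graph(nt: NeighborTable, mutual: bool = False, weighted: bool = True):
    """Undirected simple graph from a neighbor table.

    Returns a list of ``(i, j, weight)`` with ``i < j``; ``weight = 1 -
    d/max_d`` when ``weighted`` (unit weights otherwise).  ``mutual=True``
    keeps only reciprocal neighbor pairs.
    """
    n, k = nt.indices.shape
    directed = set()
    for i in range(n):
        for jj in range(k):
            directed.add((i, int(nt.indices[i, jj])))
    max_d = float(nt.distances.max()) if nt.distances.size else 0.0
    dist_of = {}
    for i in range(n):
        for jj in range(k):
            dist_of[(i, int(nt.indices[i, jj]))] = float(nt.distances[i, jj])
    edges = []
    seen = set()
    for (i, j) in sorted(directed):
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        reciprocal = (j, i) in directed
        if mutual and not reciprocal:
            continue
        seen.add(key)
        d = dist_of.get((i, j), dist_of.get((j, i)))
        w = 1.0 if not weighted else (1.0 - d / max_d if max_d > 0 else 1.0)
        edges.append((key[0], key[1], w))
    return edges


# ---------------------------------------------------------------------------
# selection


def select(X: CountMatrix, cell_mask=None, gene_mask=None) -> CountMatrix:
    """Submatrix of ``X``; ids subset in original order, caches not shared."""
    cell_idx = _as_index(cell_mask, X.n_cells, "cell")
    gene_idx = _as_index(gene_mask, X.n_genes, "gene")
    if len(cell_idx) == 0 or len(gene_idx) == 0:
        raise ValueError("empty selection")
    vals = X.values[cell_idx][:, gene_idx]
    return CountMatrix(vals, cell_ids=X.cell_ids[cell_idx], gene_ids=X.gene_ids[gene_idx])


def _as_index(mask, size, what):
    if mask is None:
        return np.arange(size)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if len(mask) != size:
            raise ValueError(f"{what} mask length {len(mask)} != {size}")
        return np.flatnonzero(mask)
    idx = mask.astype(np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= size):
        raise IndexError(f"{what} index out of bounds for size {size}")
    return idx
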