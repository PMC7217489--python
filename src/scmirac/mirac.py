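"""MIRAC: MDL iteratively regularized agglomerative clustering.

The pipeline: build a hierarchical agglomerative clustering (HAC) tree over
pairwise cell distances, optionally reorder its leaves optimally
(Bar-Joseph dynamic program), divide the tree into minimal
sub-clusters of at most ``t - 1`` cells each, then sweep the ordered
sub-clusters left to right, merging each into its left neighbor or growing
it rightward according to cross code-length similarity, and committing a
merge whenever the two-part description length satisfies

    L_divided - L_merged >= -r_minmdl * |L_merged|

(split otherwise).  Restricting candidate partitions to contiguous runs of
the leaf ordering collapses the Bell-number search space to compositions of
``n`` with all summands >= t, which the partition-counting helpers here
quantify exactly.

A community-detection extension (Leiden on a KNN graph) replaces the
per-cell sub-clusters with communities so the same merge engine scales to
large datasets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .matrix_core import CountMatrix, DistanceMatrix, array_distances, knn_graph
from .mdl_coding import (
    MergeDecision,
    matrix_cross_code_length,
    matrix_self_code_length,
    label_code_length,
)

LINKAGES = ("single", "complete", "average", "ward")

__all__ = [
    "HacTree",
    "Partition",
    "MiracParams",
    "ClusterResult",
    "PartitionCounts",
    "build_hac_tree",
    "optimal_leaf_ordering",
    "divide_tree",
    "mirac_merge",
    "mirac",
    "community_mirac",
    "bell_number",
    "compositions_min_summand",
    "partition_counts",
]


# ---------------------------------------------------------------------------
# tree


@dataclass
class HacTree:
    """Binary agglomeration tree with a linear leaf ordering."""

    linkage_matrix: np.ndarray  # scipy linkage encoding of the n-1 merges
    linkage: str
    leaf_order: np.ndarray
    order_kind: str = "dendrogram"  # or "optimal"

    @property
    def n_leaves(self) -> int:
        return self.linkage_matrix.shape[0] + 1

    def ordering_objective(self, D: DistanceMatrix) -> float:
        """Sum of distances between adjacent leaves in the current order."""
        o = self.leaf_order
        return float(D.values[o[:-1], o[1:]].sum())


def _canonical(order: np.ndarray) -> np.ndarray:
    # an ordering and its reversal are flip-equivalent; fix the direction
    return order if order[0] <= order[-1] else order[::-1]


def build_hac_tree(D: DistanceMatrix, linkage: str = "complete") -> HacTree:
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    condensed = squareform(D.values, checks=False)
    Z = sch.linkage(condensed, method=linkage)
    return HacTree(linkage_matrix=Z, linkage=linkage,
                   leaf_order=_canonical(np.asarray(sch.leaves_list(Z))),
                   order_kind="dendrogram")


def _minplus(A: np.ndarray, B: np.ndarray, chunk: int = 128) -> np.ndarray:
    """Min-plus matrix product: out[i, j] = min_k A[i, k] + B[k, j]."""
    out = np.empty((A.shape[0], B.shape[1]))
    for s in range(0, A.shape[0], chunk):
        out[s:s + chunk] = (A[s:s + chunk, :, None] + B[None, :, :]).min(axis=1)
    return out


def optimal_leaf_ordering(tree: HacTree, D: DistanceMatrix) -> HacTree:
    """Reorder leaves to minimize summed adjacent distances (Bar-Joseph DP).

    Among all 2^(n-1) orderings reachable by flipping internal nodes, the
    returned ordering attains the minimum of the sum of distances between
    adjacent leaves.  The dynamic program tabulates, per subtree, the best
    achievable cost of a leaf ordering that starts at leaf i and ends at
    leaf j (necessarily in opposite children; the matrix is symmetric
    because reversing a path keeps its cost); subtrees combine through two
    min-plus products over the cross-child distance block.
    """
    if tree.n_leaves != D.n:
        raise ValueError("tree and distance matrix sizes differ")
    Z = tree.linkage_matrix
    n = tree.n_leaves
    d = D.values
    if n <= 2:
        return HacTree(linkage_matrix=Z, linkage=tree.linkage,
                       leaf_order=np.arange(n), order_kind="optimal")

    INF = np.inf
    leaves: list = [np.array([i]) for i in range(n)] + [None] * (n - 1)
    children: dict = {}
    # cost[v][i, j]: best ordering of subtree v starting at local leaf i and
    # ending at local leaf j (positions within leaves[v]); inf if i, j fall
    # in the same child (impossible start/end pair), 0 for a singleton.
    cost: list = [np.zeros((1, 1)) for _ in range(n)] + [None] * (n - 1)
    for i in range(n - 1):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        v = n + i
        children[v] = (a, b)
        la, lb = leaves[a], leaves[b]
        leaves[v] = np.concatenate([la, lb])
        dC = d[np.ix_(la, lb)]
        S = _minplus(_minplus(cost[a], dC), cost[b])
        na, nb = len(la), len(lb)
        full = np.full((na + nb, na + nb), INF)
        full[:na, na:] = S
        full[na:, :na] = S.T
        cost[v] = full

    root = 2 * n - 2

    def order_of(v: int, start_idx: int, end_idx: int) -> list[int]:
        """Optimal leaf sequence of subtree v from local start to local end."""
        if v < n:
            return [int(leaves[v][0])]
        a, b = children[v]
        na = len(leaves[a])
        flipped = start_idx >= na
        si, sj = (end_idx, start_idx - na) if flipped else (start_idx, end_idx - na)
        la, lb = leaves[a], leaves[b]
        inner = cost[a][si][:, None] + d[np.ix_(la, lb)] + cost[b][:, sj][None, :]
        k, l = np.unravel_index(np.argmin(inner), inner.shape)
        path = order_of(a, si, int(k)) + order_of(b, int(l), sj)
        return path[::-1] if flipped else path

    i_pos, j_pos = np.unravel_index(np.argmin(cost[root]), cost[root].shape)
    leaf_order = np.asarray(order_of(root, int(i_pos), int(j_pos)))
    return HacTree(linkage_matrix=Z, linkage=tree.linkage,
                   leaf_order=_canonical(leaf_order), order_kind="optimal")


# ---------------------------------------------------------------------------
# partitions


@dataclass
class Partition:
    """Cluster assignment of n cells, optionally tied to a leaf ordering.

    For initial/final MIRAC partitions the clusters are contiguous runs of
    ``ordering``.
    """

    labels: np.ndarray
    ordering: np.ndarray | None = None
    role: str = "reference"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.ordering is not None:
            self.ordering = np.asarray(self.ordering)

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def blocks(self) -> list[np.ndarray]:
        """Clusters as lists of cell indices, in ordering sequence."""
        if self.ordering is None:
            return [np.flatnonzero(self.labels == g) for g in np.unique(self.labels)]
        lab = self.labels[self.ordering]
        cuts = np.flatnonzero(lab[1:] != lab[:-1]) + 1
        return [b for b in np.split(self.ordering, cuts)]

    @classmethod
    def from_blocks(cls, blocks, n: int, ordering=None, role="final") -> "Partition":
        labels = np.empty(n, dtype=np.int64)
        for g, blk in enumerate(blocks):
            labels[np.asarray(blk)] = g
        if ordering is None:
            ordering = np.concatenate([np.asarray(b) for b in blocks])
        return cls(labels=labels, ordering=np.asarray(ordering), role=role)

    def is_contiguous(self) -> bool:
        if self.ordering is None:
            return False
        lab = self.labels[self.ordering]
        changes = int((lab[1:] != lab[:-1]).sum())
        return changes + 1 == self.n_clusters


@dataclass
class MiracParams:
    """Tunables of the MIRAC pipeline.

    ``t`` is the minimum final cluster size (n_mincluster); ``r_minmdl``
    biases the merge/split rule toward merging: a split must reduce the
    total description length by more than ``r_minmdl * |L_merged|`` to be
    accepted.  The default 0 is the pure MDL rule (split exactly when
    dividing shortens the description); the label and two-part parameter
    costs already penalize spurious splits, and because the left cluster
    grows while the inspected cluster stays near ``t`` cells, a positive
    ratio suppresses genuine boundaries whose relative saving shrinks like
    t/|left|.  ``None`` for ``t`` selects max(5, ceil(0.01 n)) at run time.
    """

    t: int | None = None
    r_minmdl: float = 0.0
    linkage: str = "complete"
    metric: str = "cosine"
    optimal_ordering: bool = True
    ordering_threshold: int = 10_000
    division: str = "balanced"  # or "skewed"
    seed: int | None = None

    def __post_init__(self):
        if self.t is not None and self.t < 2:
            raise ValueError("t (minimum cluster size) must be >= 2")
        if self.r_minmdl < 0:
            raise ValueError("r_minmdl must be nonnegative")
        if self.division not in ("balanced", "skewed"):
            raise ValueError("division must be 'balanced' or 'skewed'")

    def resolve_t(self, n: int) -> int:
        return self.t if self.t is not None else max(5, math.ceil(0.01 * n))


@dataclass
class ClusterResult:
    partition: Partition
    tree: HacTree | None
    decisions: list[MergeDecision]
    params: MiracParams

    @property
    def labels(self) -> np.ndarray:
        return self.partition.labels


# ---------------------------------------------------------------------------
# tree division


class _Nodes:
    """Span-indexed view of a linkage tree under a fixed leaf ordering."""

    def __init__(self, Z: np.ndarray, leaf_order: np.ndarray):
        n = Z.shape[0] + 1
        self.n = n
        pos = np.empty(n, dtype=np.int64)
        pos[leaf_order] = np.arange(n)
        total = 2 * n - 1
        self.left = np.full(total, -1, dtype=np.int64)
        self.right = np.full(total, -1, dtype=np.int64)
        self.start = np.empty(total, dtype=np.int64)
        self.end = np.empty(total, dtype=np.int64)
        self.count = np.empty(total, dtype=np.int64)
        self.start[:n] = pos
        self.end[:n] = pos
        self.count[:n] = 1
        for i in range(n - 1):
            a, b = int(Z[i, 0]), int(Z[i, 1])
            v = n + i
            self.left[v], self.right[v] = a, b
            self.start[v] = min(self.start[a], self.start[b])
            self.end[v] = max(self.end[a], self.end[b])
            self.count[v] = self.count[a] + self.count[b]
            if self.end[v] - self.start[v] + 1 != self.count[v]:
                raise ValueError("leaf ordering is not consistent with the tree")
        self.leaf_order = leaf_order
        self.root = total - 1

    def children_in_order(self, v: int) -> tuple[int, int]:
        a, b = self.left[v], self.right[v]
        return (a, b) if self.start[a] <= self.start[b] else (b, a)

    def leaves(self, v: int) -> np.ndarray:
        return self.leaf_order[self.start[v]: self.end[v] + 1]


def divide_tree(tree: HacTree, t: int, mode: str = "balanced") -> Partition:
    """Divide the tree into contiguous sub-clusters of at most ``t - 1`` cells.

    ``balanced`` recursively splits every oversized node at its two
    children.  ``skewed`` first detaches, within each oversized node, the
    minimum subtree holding >= t leaves, so a small tight group hanging off
    the root is isolated early instead of being split across its sibling.
    """
    if t < 2:
        raise ValueError("t must be >= 2")
    nd = _Nodes(tree.linkage_matrix, tree.leaf_order)
    blocks: list[np.ndarray] = []

    if mode == "balanced":
        def rec(v: int):
            if nd.count[v] <= t - 1:
                blocks.append(nd.leaves(v))
                return
            a, b = nd.children_in_order(v)
            rec(a)
            rec(b)
        rec(nd.root)
    elif mode == "skewed":
        # minimal descendant (incl. self) with >= t leaves, per node
        minsub = np.full(2 * nd.n - 1, -1, dtype=np.int64)
        for v in range(2 * nd.n - 1):
            if nd.count[v] < t:
                continue
            best = v
            for c in (nd.left[v], nd.right[v]):
                if c >= 0 and minsub[c] >= 0 and nd.count[minsub[c]] < nd.count[best]:
                    best = minsub[c]
            minsub[v] = best

        def rec(v: int):
            if nd.count[v] <= t - 1:
                blocks.append(nd.leaves(v))
                return
            u = int(minsub[v])
            if u == v:
                a, b = nd.children_in_order(v)
                rec(a)
                rec(b)
                return
            # siblings hanging off the path v -> u, plus u itself
            pieces = []
            w = v
            while w != u:
                a, b = nd.left[w], nd.right[w]
                down = a if (nd.start[a] <= nd.start[u] <= nd.end[a]) else b
                pieces.append(b if down == a else a)
                w = down
            pieces.append(u)
            for p in sorted(pieces, key=lambda q: nd.start[q]):
                rec(p)
        rec(nd.root)
    else:
        raise ValueError("mode must be 'balanced' or 'skewed'")

    blocks.sort(key=lambda blk: int(np.flatnonzero(tree.leaf_order == blk[0])[0]))
    return Partition.from_blocks(blocks, nd.n, ordering=tree.leaf_order, role="initial")


# ---------------------------------------------------------------------------
# merging


def _as_dense(X) -> np.ndarray:
    if isinstance(X, CountMatrix):
        return X.toarray()
    return np.asarray(X, dtype=np.float64)


def _mdl_test(A: np.ndarray, left: np.ndarray, cur: np.ndarray, r: float) -> MergeDecision:
    rows = np.concatenate([left, cur])
    sub = A[rows]
    l_m = label_code_length(np.zeros(len(rows))) + matrix_self_code_length(sub)
    lab = np.concatenate([np.zeros(len(left)), np.ones(len(cur))])
    l_d = label_code_length(lab) + matrix_self_code_length(A[left]) + matrix_self_code_length(A[cur])
    merged = (l_d - l_m) >= -r * abs(l_m)
    return MergeDecision(l_merged=l_m, l_divided=l_d, r_minmdl=r, merged=merged,
                         left_size=len(left), right_size=len(cur))


def mirac_merge(X, P_s: Partition, params: MiracParams) -> tuple[Partition, list[MergeDecision]]:
    """Iteratively merge the ordered sub-clusters of ``P_s`` into final clusters.

    Head and tail sub-clusters are first accumulated to >= t cells.  Each
    middle sub-cluster below t cells is compared (by cross code length) to
    the growing left cluster versus the right-minimax union of following
    sub-clusters and absorbed toward the more similar side; once it reaches
    t cells the two-part MDL merge/split test against the left cluster is
    applied.  Every returned cluster has >= t cells whenever n >= 2t.
    """
    A = _as_dense(X)
    n = A.shape[0]
    t = params.resolve_t(n)
    r = params.r_minmdl
    blocks = [np.asarray(b) for b in P_s.blocks()]
    ordering = P_s.ordering if P_s.ordering is not None else np.concatenate(blocks)

    if n < 2 * t:
        warnings.warn(f"n={n} < 2t={2 * t}: returning a single cluster")
        return Partition.from_blocks([np.concatenate(blocks)], n, ordering, role="final"), []

    # head accumulation: merge leading sub-clusters until >= t cells
    i = 0
    head_parts: list[np.ndarray] = []
    while i < len(blocks) and sum(map(len, head_parts)) < t:
        head_parts.append(blocks[i])
        i += 1
    head = np.concatenate(head_parts)
    if i >= len(blocks):
        warnings.warn("head accumulation consumed all cells; single cluster")
        return Partition.from_blocks([ordering.copy()], n, ordering, role="final"), []
    # tail accumulation: merge trailing sub-clusters until >= t cells
    j = len(blocks)
    tail_parts: list[np.ndarray] = []
    while j > i and sum(map(len, tail_parts)) < t:
        j -= 1
        tail_parts.insert(0, blocks[j])
    tail = np.concatenate(tail_parts)
    middle = [blocks[q] for q in range(i, j)]

    decisions: list[MergeDecision] = []
    final: list[np.ndarray] = []
    left = head
    queue = middle + [tail]
    qi = 0
    while qi < len(queue):
        cur = queue[qi]
        is_tail = qi == len(queue) - 1
        if len(cur) < t and not is_tail:
            # right-minimax: smallest union of following clusters with >= t cells
            rmm = []
            total = 0
            for fut in queue[qi + 1:]:
                rmm.append(fut)
                total += len(fut)
                if total >= t:
                    break
            rmm_rows = np.concatenate(rmm)
            sim_left = matrix_cross_code_length(A[cur], A[left])
            sim_right = matrix_cross_code_length(A[cur], A[rmm_rows])
            if sim_left <= sim_right:
                left = np.concatenate([left, cur])
            else:
                # more similar to the right: grow into the next sub-cluster
                queue[qi + 1] = np.concatenate([cur, queue[qi + 1]])
            qi += 1
            continue
        # |cur| >= t (or cur is the tail): two-part MDL merge/split test
        dec = _mdl_test(A, left, cur, r)
        decisions.append(dec)
        if dec.merged:
            left = np.concatenate([left, cur])
        else:
            final.append(left)
            left = cur
        qi += 1
    final.append(left)
    # guarantee: a tail that never reached t cells cannot stand alone
    if len(final) > 1 and len(final[-1]) < t:
        small = final.pop()
        final[-1] = np.concatenate([final[-1], small])

    # restore ordering sequence within blocks
    pos = np.empty(n, dtype=np.int64)
    pos[ordering] = np.arange(n)
    final = [blk[np.argsort(pos[blk])] for blk in final]
    final.sort(key=lambda blk: pos[blk[0]])
    part = Partition.from_blocks(final, n, ordering, role="final")
    return part, decisions


def mirac(X, params: MiracParams | None = None, embedding=None) -> ClusterResult:
    """Run the full MIRAC pipeline on a count matrix.

    Distances (and the HAC tree) are computed on ``embedding`` when given,
    otherwise on ``X`` itself; code lengths are always computed on ``X``.
    """
    params = params or MiracParams()
    A = _as_dense(X)
    n = A.shape[0]
    if isinstance(X, CountMatrix) and embedding is None:
        D = X.pairwise_distances(params.metric)
    else:
        vals = np.asarray(embedding, dtype=np.float64) if embedding is not None else A
        D = DistanceMatrix(metric=params.metric,
                           values=array_distances(vals, params.metric))
    tree = build_hac_tree(D, params.linkage)
    if params.optimal_ordering and n <= params.ordering_threshold:
        tree = optimal_leaf_ordering(tree, D)
    t = params.resolve_t(n)
    P_s = divide_tree(tree, t, params.division)
    P_g, decisions = mirac_merge(A, P_s, params)
    return ClusterResult(partition=P_g, tree=tree, decisions=decisions, params=params)


# ---------------------------------------------------------------------------
# community-detection extension


def _leiden_communities(edges, n, resolution, seed):
    import igraph
    import leidenalg

    g = igraph.Graph(n=n, edges=[(i, j) for i, j, _ in edges])
    weights = [w for _, _, w in edges]
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=weights, resolution_parameter=resolution,
        seed=int(seed) if seed is not None else 0,
    )
    return np.asarray(part.membership)


def community_mirac(X, params: MiracParams | None = None, k: int = 15,
                    min_communities: int | None = None, embedding=None) -> ClusterResult:
    """MIRAC over Leiden communities of the KNN graph instead of single cells.

    Communities are atomic: an HAC tree over community centroids fixes their
    order, and the merge engine pools member rows when computing code
    lengths, so the final clusters are unions of communities mapped back to
    cells.
    """
    params = params or MiracParams()
    A = _as_dense(X)
    n = A.shape[0]
    data = np.asarray(embedding, dtype=np.float64) if embedding is not None else A
    if min_communities is None:
        min_communities = min(max(20, math.ceil(n / 1000)), 500, max(2, n // 2))
    D = DistanceMatrix(metric=params.metric, values=array_distances(data, params.metric))
    from .matrix_core import _exact_knn

    idx, dist = _exact_knn(D.values, min(k, n - 1))
    from .matrix_core import NeighborTable

    edges = knn_graph(NeighborTable(k=idx.shape[1], indices=idx, distances=dist))

    # resolution search: Leiden community count grows with resolution
    def count_at(res):
        return _leiden_communities(edges, n, res, params.seed)

    lo, hi = 1e-3, 4.0
    memb = count_at(hi)
    tries = 0
    while len(np.unique(memb)) < min_communities and tries < 8:
        hi *= 4.0
        memb = count_at(hi)
        tries += 1
    if len(np.unique(memb)) >= min_communities:
        best = memb
        for _ in range(20):
            mid = math.sqrt(lo * hi)
            m = count_at(mid)
            if len(np.unique(m)) >= min_communities:
                best, hi = m, mid
            else:
                lo = mid
        memb = best
    else:
        warnings.warn(
            f"could not reach {min_communities} communities by resolution search; "
            f"proceeding with {len(np.unique(memb))}"
        )

    comms = [np.flatnonzero(memb == g) for g in np.unique(memb)]
    centroids = np.vstack([data[c].mean(axis=0) for c in comms])
    tree = None
    if len(comms) > 1:
        Dc = DistanceMatrix(metric=params.metric,
                            values=array_distances(centroids, params.metric))
        tree = build_hac_tree(Dc, params.linkage)
        tree = optimal_leaf_ordering(tree, Dc)
        comms = [comms[i] for i in tree.leaf_order]
    ordering = np.concatenate(comms)
    P_s = Partition.from_blocks(comms, n, ordering, role="initial")
    P_g, decisions = mirac_merge(A, P_s, params)
    return ClusterResult(partition=P_g, tree=tree, decisions=decisions, params=params)


# ---------------------------------------------------------------------------
# partition counting


def bell_number(n: int) -> int:
    """Number of unordered set partitions of n items (exact integers)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    B = [1]  # B_0
    for nn in range(1, n + 1):
        B.append(sum(B[k] * math.comb(nn - 1, k) for k in range(nn)))
    return B[n]


def compositions_min_summand(n: int, t: int) -> int:
    """Number of compositions of n with every summand >= t (exact integers).

    At t=1 this reduces to the unconstrained composition count 2^(n-1).
    """
    if n < 1 or t < 1:
        raise ValueError("require n >= 1 and t >= 1")
    return sum(math.comb(n - k * (t - 1) - 1, k - 1) for k in range(1, n // t + 1))


@dataclass
class PartitionCounts:
    """How each MIRAC restriction shrinks the candidate-partition space."""

    n: int
    t: int
    bell: int
    compositions: int
    compositions_min_t: int


def partition_counts(n: int, t: int) -> PartitionCounts:
    return PartitionCounts(
        n=n, t=t,
        bell=bell_number(n),
        compositions=2 ** (n - 1) if n >= 1 else 0,
        compositions_min_t=compositions_min_summand(n, t),
    )
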