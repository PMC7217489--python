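import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from scmirac.matrix_core import CountMatrix, DistanceMatrix, array_distances
from scmirac.mirac import (
    MiracParams,
    Partition,
    bell_number,
    build_hac_tree,
    community_mirac,
    compositions_min_summand,
    divide_tree,
    mirac,
    mirac_merge,
    optimal_leaf_ordering,
    partition_counts,
)


def _dm(points, metric="euclidean"):
    return DistanceMatrix(metric=metric,
                          values=array_distances(np.asarray(points, dtype=float), metric))


def _all_flip_orderings(Z):
    """Every leaf ordering reachable by flipping internal nodes (brute force)."""
    n = Z.shape[0] + 1

    def orders(node):
        if node < n:
            return [[node]]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        out = []
        for x in orders(a):
            for y in orders(b):
                out.append(x + y)
                out.append(y + x)
        return out

    return orders(2 * n - 2)


# ---------------------------------------------------------------------------
# tree building and ordering


class TestBuildHacTree:
    def test_two_points_single_merge(self):
        tree = build_hac_tree(_dm([[0.0], [1.0]]))
        assert tree.n_leaves == 2
        assert sorted(tree.leaf_order) == [0, 1]

    def test_single_linkage_merges_close_pairs_first(self):
        tree = build_hac_tree(_dm([[0.0], [1.0], [10.0], [11.0]]), "single")
        Z = tree.linkage_matrix
        first_two = {frozenset(map(int, Z[0, :2])), frozenset(map(int, Z[1, :2]))}
        assert frozenset({0, 1}) in first_two
        assert frozenset({2, 3}) in first_two

    def test_invalid_linkage(self):
        with pytest.raises(ValueError, match="unknown linkage"):
            build_hac_tree(_dm([[0.0], [1.0]]), "centroidish")

    def test_cophenetic_structure_permutation_invariant_without_ties(self, rng):
        from scipy.cluster.hierarchy import cophenet
        pts = rng.normal(size=(12, 3)) * 10
        coph = squareform(cophenet(build_hac_tree(_dm(pts)).linkage_matrix))
        perm = rng.permutation(12)
        coph_p = squareform(cophenet(build_hac_tree(_dm(pts[perm])).linkage_matrix))
        np.testing.assert_allclose(coph_p, coph[np.ix_(perm, perm)])


class TestOptimalLeafOrdering:
    def test_n2_lower_index_first(self):
        tree = build_hac_tree(_dm([[0.0], [1.0]]))
        olo = optimal_leaf_ordering(tree, _dm([[0.0], [1.0]]))
        assert list(olo.leaf_order) == [0, 1]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        D = _dm(rng.normal(size=(n, 2)) * 5)
        tree = build_hac_tree(D)
        olo = optimal_leaf_ordering(tree, D)
        best = min(sum(D.values[o[i], o[i + 1]] for i in range(n - 1))
                   for o in _all_flip_orderings(olo.linkage_matrix))
        assert olo.ordering_objective(D) == pytest.approx(best)
        assert olo.order_kind == "optimal"

    def test_never_worse_than_dendrogram_default(self, rng):
        pts = rng.normal(size=(15, 4))
        D = _dm(pts)
        tree = build_hac_tree(D)
        olo = optimal_leaf_ordering(tree, D)
        assert olo.ordering_objective(D) <= tree.ordering_objective(D) + 1e-12

    def test_size_mismatch(self, rng):
        tree = build_hac_tree(_dm(rng.normal(size=(5, 2))))
        with pytest.raises(ValueError, match="sizes differ"):
            optimal_leaf_ordering(tree, _dm(rng.normal(size=(6, 2))))


# ---------------------------------------------------------------------------
# tree division


class TestDivideTree:
    def test_small_tree_single_cluster(self, rng):
        pts = rng.normal(size=(5, 2))
        D = _dm(pts)
        part = divide_tree(build_hac_tree(D), t=6)
        assert part.n_clusters == 1

    def test_balanced_tree_division(self):
        pts = [[0.0], [1.0], [10.0], [11.0], [100.0], [101.0], [1000.0], [1001.0]]
        D = _dm(pts)
        part = divide_tree(build_hac_tree(D), t=3)
        sizes = np.bincount(part.labels)
        assert (sizes <= 2).all()
        assert part.n_clusters >= 4

    @pytest.mark.parametrize("mode", ["balanced", "skewed"])
    @pytest.mark.parametrize("t", [2, 3, 5, 9])
    def test_postconditions_on_random_instances(self, rng, mode, t):
        pts = rng.normal(size=(30, 3))
        D = _dm(pts)
        tree = build_hac_tree(D)
        part = divide_tree(tree, t=t, mode=mode)
        sizes = np.bincount(part.labels)
        assert sizes.max() <= t - 1
        assert math.ceil(30 / (t - 1)) <= part.n_clusters <= 30
        assert part.is_contiguous()
        assert sizes.min() >= 1

    def test_invalid_t(self, rng):
        tree = build_hac_tree(_dm(rng.normal(size=(5, 2))))
        with pytest.raises(ValueError, match="t must be"):
            divide_tree(tree, t=1)


# ---------------------------------------------------------------------------
# merging and the full pipeline


def _blobs(rng, n_per=60, m=20, rates=(3.0, 30.0)):
    X = np.vstack([rng.poisson(r, size=(n_per, m)) for r in rates]).astype(float)
    labels = np.repeat(np.arange(len(rates)), n_per)
    return CountMatrix(X), labels


class TestMiracMerge:
    @pytest.mark.parametrize("seed", range(10))
    def test_two_separated_blobs_recovered(self, seed):
        rng = np.random.default_rng(seed)
        X, truth = _blobs(rng)
        res = mirac(X, MiracParams(t=10, metric="euclidean"))
        from scmirac.metrics_eval import ari
        assert ari(truth, res.labels) == pytest.approx(1.0)

    def test_logged_decisions_arithmetically_consistent(self, rng):
        X, _ = _blobs(rng)
        res = mirac(X, MiracParams(t=10, metric="euclidean"))
        assert len(res.decisions) >= 1
        assert all(d.consistent() for d in res.decisions)

    def test_min_cluster_size_honored(self, rng):
        X, _ = _blobs(rng, n_per=40)
        res = mirac(X, MiracParams(t=12, metric="euclidean"))
        assert np.bincount(res.labels).min() >= 12

    def test_final_clusters_contiguous_in_leaf_order(self, rng):
        X, _ = _blobs(rng)
        res = mirac(X, MiracParams(t=10, metric="euclidean"))
        assert res.partition.is_contiguous()

    def test_small_n_returns_single_cluster_with_warning(self, rng):
        X = CountMatrix(rng.poisson(5.0, size=(8, 4)).astype(float))
        with pytest.warns(UserWarning, match="single cluster"):
            res = mirac(X, MiracParams(t=5))
        assert res.partition.n_clusters == 1


class TestMiracPipeline:
    def test_identical_rows_single_cluster(self):
        X = CountMatrix(np.tile([3.0, 1.0, 4.0], (30, 1)))
        res = mirac(X, MiracParams(t=5, metric="euclidean"))
        assert res.partition.n_clusters == 1

    def test_deterministic_rerun(self, rng):
        X, _ = _blobs(rng)
        p = MiracParams(t=10, metric="euclidean", seed=7)
        r1 = mirac(X, p)
        r2 = mirac(X, p)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_row_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(5)
        X, _ = _blobs(rng)
        perm = rng.permutation(X.n_cells)
        r1 = mirac(X, MiracParams(t=10, metric="euclidean"))
        r2 = mirac(CountMatrix(X.toarray()[perm]), MiracParams(t=10, metric="euclidean"))
        from scmirac.metrics_eval import ari
        assert ari(r1.labels[perm], r2.labels) == pytest.approx(1.0)

    def test_embedding_drives_distances(self, rng):
        # counts are uninformative; a separated 2-D embedding should decide
        X = CountMatrix(rng.poisson(5.0, size=(60, 5)).astype(float))
        emb = np.vstack([rng.normal(0, 0.1, size=(30, 2)),
                         rng.normal(50, 0.1, size=(30, 2))])
        res = mirac(X, MiracParams(t=10, metric="euclidean"), embedding=emb)
        assert res.tree is not None

    def test_ordering_skipped_above_threshold(self, rng):
        X, _ = _blobs(rng, n_per=20)
        res = mirac(X, MiracParams(t=8, metric="euclidean", ordering_threshold=10))
        assert res.tree.order_kind == "dendrogram"


class TestCommunityMirac:
    def test_two_blobs_two_clusters(self):
        rng = np.random.default_rng(0)
        X, truth = _blobs(rng, n_per=50)
        res = community_mirac(X, MiracParams(t=10, metric="euclidean", seed=0),
                              k=8, min_communities=6)
        from scmirac.metrics_eval import ari
        assert ari(truth, res.labels) == pytest.approx(1.0)

    def test_single_blob_single_cluster(self, rng):
        X = CountMatrix(rng.poisson(10.0, size=(60, 10)).astype(float))
        res = community_mirac(X, MiracParams(t=10, metric="euclidean", seed=0),
                              k=8, min_communities=1)
        assert res.partition.n_clusters == 1

    def test_agrees_with_plain_mirac_on_separable_data(self):
        rng = np.random.default_rng(3)
        X, _ = _blobs(rng, n_per=60)
        p = MiracParams(t=10, metric="euclidean", seed=3)
        r_plain = mirac(X, p)
        r_comm = community_mirac(X, p, k=8, min_communities=6)
        from scmirac.metrics_eval import ari
        assert ari(r_plain.labels, r_comm.labels) >= 0.9


# ---------------------------------------------------------------------------
# partition counting


def _count_set_partitions(n):
    """Brute-force Bell number: enumerate partitions by restricted growth."""
    def rec(i, maxg):
        if i == n:
            return 1
        return sum(rec(i + 1, max(maxg, g + 1)) for g in range(maxg + 1))
    return rec(0, 0) if n > 0 else 1


def _count_compositions(n, t):
    def rec(rem):
        if rem == 0:
            return 1
        return sum(rec(rem - p) for p in range(t, rem + 1))
    return rec(n)


class TestPartitionCounting:
    def test_bell_base_cases_and_small_values(self):
        assert bell_number(0) == 1
        assert bell_number(1) == 1
        assert bell_number(3) == 5

    @pytest.mark.parametrize("n", range(7))
    def test_bell_matches_enumeration(self, n):
        assert bell_number(n) == _count_set_partitions(n)

    def test_bell_negative_errors(self):
        with pytest.raises(ValueError):
            bell_number(-1)

    def test_printed_constrained_values(self):
        assert compositions_min_summand(60, 20) == 23
        assert compositions_min_summand(100, 20) == 2695
        assert compositions_min_summand(200, 20) == 194570810

    def test_unconstrained_reduction(self):
        assert compositions_min_summand(21, 1) == 2 ** 20 == 1048576
        for n in (1, 5, 10):
            assert compositions_min_summand(n, 1) == 2 ** (n - 1)

    def test_small_case_by_hand(self):
        assert compositions_min_summand(4, 2) == 2  # 4 and 2+2

    def test_matches_enumeration_up_to_14(self):
        for n in range(1, 15):
            for t in range(1, n + 1):
                assert compositions_min_summand(n, t) == _count_compositions(n, t)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            compositions_min_summand(0, 1)

    def test_partition_counts_bundle(self):
        pc = partition_counts(10, 3)
        assert pc.bell == bell_number(10)
        assert pc.compositions == 2 ** 9
        assert pc.compositions_min_t == compositions_min_summand(10, 3)
        assert isinstance(pc.bell, int)
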