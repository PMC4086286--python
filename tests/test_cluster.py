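import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from hvtime.cluster import (
    HierarchicalClustering,
    hierarchical_cluster,
    mean_center,
    pairwise_uncentered_distance,
    uncentered_correlation,
)
from hvtime.errors import ZeroVector


def _merged_sets(merges, n):
    member = {i: frozenset([i]) for i in range(n)}
    out = set()
    for a, b, d, new in merges:
        member[new] = member[a] | member[b]
        out.add(member[new])
    return out


class TestMeanCenter:
    @pytest.mark.parametrize(
        "row, expected",
        [([1, 2, 3], [-1, 0, 1]), ([5, 5], [0, 0]), ([-1, 0, 1], [-1, 0, 1])],
    )
    def test_examples(self, row, expected):
        np.testing.assert_allclose(mean_center(row), expected)

    def test_sums_to_zero(self):
        x = np.random.default_rng(0).normal(5, 2, 100)
        assert abs(mean_center(x).sum()) < 1e-12


class TestUncenteredCorrelation:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 0], [0, 1], 0.0),
            ([1, 2], [-1, -2], -1.0),
        ],
    )
    def test_examples(self, x, y, expected):
        assert uncentered_correlation(x, y) == pytest.approx(expected)

    def test_zero_vector(self):
        with pytest.raises(ZeroVector):
            uncentered_correlation([0, 0], [1, 2])

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x, y = rng.normal(size=(2, 8))
            s = uncentered_correlation(x, y)
            assert s == pytest.approx(uncentered_correlation(y, x))
            assert -1.0 <= s <= 1.0

    @pytest.mark.parametrize("c", [0.01, 2.0, 1e6])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 10))
        assert uncentered_correlation(c * x, y) == pytest.approx(
            uncentered_correlation(x, y)
        )


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        X = np.array([[1.0, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1], [0, 1, 0, 1]])
        tree = hierarchical_cluster(X)
        a, b, d, _ = tree.merges[0]
        assert {a, b} == {0, 1} and d == pytest.approx(0.0, abs=1e-12)

    def test_merge_heights_non_decreasing_and_bounded(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 6))
        tree = hierarchical_cluster(X)
        heights = [m[2] for m in tree.merges]
        assert all(h1 <= h2 + 1e-12 for h1, h2 in zip(heights, heights[1:]))
        assert all(0.0 <= h <= 2.0 + 1e-12 for h in heights)

    def test_matches_scipy_average_linkage(self):
        # independent oracle: scipy's agglomerator on the same distances
        rng = np.random.default_rng(4)
        for _ in range(50):
            X = rng.normal(size=(6, 4))
            tree = hierarchical_cluster(X)
            D = pairwise_uncentered_distance(X)
            Z = linkage(squareform(D, checks=False), method="average")
            np.testing.assert_allclose(
                sorted(m[2] for m in tree.merges), sorted(Z[:, 2]), atol=1e-12
            )
            scipy_merges = [
                (int(a), int(b), d, 6 + i) for i, (a, b, d, _) in enumerate(Z)
            ]
            assert _merged_sets(tree.merges, 6) == _merged_sets(scipy_merges, 6)

    def test_duplicate_leaf_contraction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(7, 5))
        base = hierarchical_cluster(X)
        ext = hierarchical_cluster(np.vstack([X, X[2]]))  # duplicate row 2 -> leaf 7
        ext_sets = {frozenset(s - {7}) for s in _merged_sets(ext.merges, 8)}
        base_sets = _merged_sets(base.merges, 7)
        assert base_sets <= ext_sets
        # the duplicate merges with its original at distance 0 first
        a, b, d, _ = ext.merges[0]
        assert {a, b} == {2, 7} and d == pytest.approx(0.0, abs=1e-12)

    def test_row_scaling_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 5))
        scales = rng.uniform(0.1, 10.0, size=(10, 1))
        t1 = hierarchical_cluster(X)
        t2 = hierarchical_cluster(X * scales)
        assert [m[:2] for m in t1.merges] == [m[:2] for m in t2.merges]
        np.testing.assert_allclose(
            [m[2] for m in t1.merges], [m[2] for m in t2.merges], atol=1e-12
        )

    def test_zero_row_rejected(self):
        with pytest.raises(ZeroVector):
            hierarchical_cluster(np.array([[1.0, 2.0], [0.0, 0.0]]))


class TestEstimatorAndTree:
    def test_leaf_order_and_newick(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 5))
        est = HierarchicalClustering().fit(X)
        order = est.leaf_order_
        assert sorted(order) == sorted(est.tree_.leaf_ids)
        nwk = est.tree_.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 7

    def test_newick_branch_lengths_split_merge_distance(self):
        # ultrametric check: every leaf sits at depth root_height / 2
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 4))
        tree = hierarchical_cluster(X)
        import io

        from Bio import Phylo

        t = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        root_h = tree.merges[-1][2]
        for leaf in t.get_terminals():
            assert t.distance(t.root, leaf) == pytest.approx(root_h / 2, abs=1e-9)
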