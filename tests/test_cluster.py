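"""Correlation-distance clustering: hierarchical, k-means, k selection, Newick."""

import io

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo
from sklearn.metrics import adjusted_rand_score, silhouette_score

from netact.activity import standardize
from netact.cluster import (
    Dendrogram,
    bicluster,
    correlation_distance,
    cut_tree,
    export_newick,
    hcluster_complete,
    kmeans_correlation,
    select_k,
)

from conftest import brute_force_complete_linkage, random_distance_matrix


def three_point_distance():
    # d(A,B)=1, d(A,C)=5, d(B,C)=4: merge {A,B} at 1, then C at max(5,4)=5
    return pd.DataFrame(
        [[0.0, 1.0, 5.0], [1.0, 0.0, 4.0], [5.0, 4.0, 0.0]],
        index=list("ABC"), columns=list("ABC"),
    )


def blobs(n_features=8, n_per_group=15, shift=4.0, seed=0):
    """Two sample groups, each sharing its own strong feature pattern."""
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 1, (n_features, 2 * n_per_group))
    for g in (0, 1):
        pattern = rng.normal(0, 1, n_features) * shift
        cols = slice(g * n_per_group, (g + 1) * n_per_group)
        base[:, cols] += pattern[:, None]
    X = pd.DataFrame(base, columns=[f"s{j}" for j in range(2 * n_per_group)])
    truth = np.repeat([0, 1], n_per_group)
    return X, truth


class TestCorrelationDistance:
    def test_identical_columns_zero(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert correlation_distance(X).loc["a", "b"] == pytest.approx(0.0)

    def test_anticorrelated_columns_two(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [-1.0, -2.0, -3.0]})
        assert correlation_distance(X).loc["a", "b"] == pytest.approx(2.0)

    def test_spearman_hand_example(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 3.0, 2.0]})
        d = correlation_distance(X, method="spearman")
        assert d.loc["a", "b"] == pytest.approx(0.5)

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "bad": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="bad"):
            correlation_distance(X)


class TestHierarchical:
    def test_three_point_worked_example(self):
        dend = hcluster_complete(three_point_distance())
        heights = [m[2] for m in dend.merges()]
        assert heights == pytest.approx([1.0, 5.0])
        labels = cut_tree(dend, 2)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_two_points(self):
        d = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        dend = hcluster_complete(d)
        assert dend.merges()[0][2] == pytest.approx(0.7)

    def test_duplicate_points_merge_at_zero(self):
        d = pd.DataFrame(
            [[0.0, 0.0, 2.0], [0.0, 0.0, 2.0], [2.0, 2.0, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        assert hcluster_complete(d).merges()[0][2] == pytest.approx(0.0)

    def test_matches_brute_force_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            d = random_distance_matrix(rng, n)
            heights, partitions = brute_force_complete_linkage(d)
            dend = hcluster_complete(d)
            np.testing.assert_allclose(
                [m[2] for m in dend.merges()], heights, rtol=1e-10
            )
            for k, expected in zip(range(n - 1, 0, -1), partitions):
                got = cut_tree(dend, k)
                got_partition = frozenset(
                    frozenset(got.index[got == c]) for c in got.unique()
                )
                assert got_partition == expected

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            d = random_distance_matrix(rng, int(rng.integers(4, 12)))
            heights = [m[2] for m in hcluster_complete(d).merges()]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))


class TestCutTree:
    def test_extremes_and_bounds(self):
        dend = hcluster_complete(three_point_distance())
        assert cut_tree(dend, 3).nunique() == 3
        assert cut_tree(dend, 1).nunique() == 1
        with pytest.raises(ValueError):
            cut_tree(dend, 0)
        with pytest.raises(ValueError):
            cut_tree(dend, 4)


class TestBicluster:
    def test_recovers_planted_sample_groups(self):
        X, truth = blobs(seed=1)
        _, col_dend, _ = bicluster(X)
        labels = cut_tree(col_dend, 2)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_minimal_matrix(self):
        X = pd.DataFrame([[1.0, 2.0], [5.0, 3.0]], index=["r1", "r2"],
                         columns=["c1", "c2"])
        row_dend, col_dend, ordered = bicluster(X)
        assert row_dend.n_leaves == col_dend.n_leaves == 2
        assert ordered.shape == (2, 2)

    def test_transpose_swaps_dendrograms(self):
        # exact symmetry on the raw scale (row standardization is per-feature
        # affine, so it would preserve the row tree but not the column tree)
        X, _ = blobs(n_features=6, n_per_group=5, seed=2)
        X.index = [f"f{i}" for i in range(6)]
        row_d, col_d, _ = bicluster(X, standardize_first=False)
        row_t, col_t, _ = bicluster(X.T, standardize_first=False)
        assert row_t.leaf_order == col_d.leaf_order
        assert col_t.leaf_order == row_d.leaf_order


class TestKMeans:
    def test_recovers_two_blobs(self):
        X, truth = blobs(seed=3)
        result = kmeans_correlation(X, 2, n_restarts=10, seed=0)
        assert adjusted_rand_score(truth, result.assignments.to_numpy()) == 1.0

    def test_duplication_invariance(self):
        X, _ = blobs(n_per_group=8, seed=4)
        doubled = pd.concat(
            [X, X.rename(columns=lambda c: c + "_dup")], axis=1
        )
        result = kmeans_correlation(doubled, 2, n_restarts=10, seed=0)
        a = result.assignments
        for c in X.columns:
            assert a[c] == a[c + "_dup"]

    def test_k_equals_n_zero_inertia(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        result = kmeans_correlation(X, 4, n_restarts=5, seed=0)
        assert result.inertia == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        X, _ = blobs(seed=6)
        r1 = kmeans_correlation(X, 3, n_restarts=5, seed=42)
        r2 = kmeans_correlation(X, 3, n_restarts=5, seed=42)
        pd.testing.assert_series_equal(r1.assignments, r2.assignments)
        assert r1.inertia == r2.inertia

    def test_best_of_restarts_monotone(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(5, 40)))
        X.columns = [f"s{j}" for j in range(40)]
        inertias = [
            kmeans_correlation(X, 4, n_restarts=r, seed=0).inertia
            for r in (1, 5, 20)
        ]
        assert inertias[0] >= inertias[1] >= inertias[2] - 1e-12

    def test_validation(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError, match="k must be"):
            kmeans_correlation(X, 1)
        with pytest.raises(ValueError, match="cannot form"):
            kmeans_correlation(X, 5)


class TestSelectK:
    def planted(self, n_groups, seed=0, n_per_group=12):
        rng = np.random.default_rng(seed)
        n_features = 8
        cols = []
        for g in range(n_groups):
            pattern = rng.normal(0, 1, n_features) * 4.0
            cols.append(pattern[:, None] + rng.normal(0, 1, (n_features, n_per_group)))
        X = pd.DataFrame(np.hstack(cols),
                         columns=[f"s{j}" for j in range(n_groups * n_per_group)])
        return X

    @pytest.mark.parametrize("n_groups", [2, 3])
    def test_finds_planted_group_count(self, n_groups):
        X = self.planted(n_groups)
        report = select_k(X, (2, 6), seed=0, n_restarts=10)
        assert report.chosen_k == n_groups
        assert all(-1 <= s <= 1 for s in report.silhouette_by_k.values())

    def test_chosen_k_attains_maximum(self):
        X = self.planted(2, seed=1)
        report = select_k(X, (2, 5), seed=0, n_restarts=10)
        assert report.silhouette_by_k[report.chosen_k] == max(
            report.silhouette_by_k.values()
        )

    def test_range_validation(self):
        X = self.planted(2)
        with pytest.raises(ValueError):
            select_k(X, (1, 4))


class TestNewick:
    def test_two_leaves(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        assert export_newick(hcluster_complete(d)) == "(A:0.5,B:0.5);"

    def test_three_leaf_topology_and_parseable(self):
        tree = Phylo.read(
            io.StringIO(export_newick(hcluster_complete(three_point_distance()))),
            "newick",
        )
        names = {t.name for t in tree.get_terminals()}
        assert names == {"A", "B", "C"}
        # A and B form a cherry below C's attachment
        ab = tree.common_ancestor(["A", "B"])
        assert {t.name for t in ab.get_terminals()} == {"A", "B"}
        # leaf depths equal the root radius (ultrametric, height 5 -> 2.5)
        assert tree.distance("A") == pytest.approx(2.5)
        assert tree.distance("C") == pytest.approx(2.5)

    def test_names_with_spaces_quoted(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]],
                         index=["sample 1", "B"], columns=["sample 1", "B"])
        out = export_newick(hcluster_complete(d))
        assert "'sample 1'" in out
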