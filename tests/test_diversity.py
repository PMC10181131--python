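"""Distances, UPGMA and PCA against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from tetrafinger.diversity import (Dendrogram, euclidean_distances,
                                   pca_scores, upgma)


def _brute_force_distance(x, y):
    total, shared = 0.0, 0
    for a, b in zip(x, y):
        if not (math.isnan(a) or math.isnan(b)):
            total += (a - b) ** 2
            shared += 1
    return (math.sqrt(total) if shared else math.nan), shared


def _random_matrix(n, m, seed, missing_rate=0.0):
    rng = np.random.default_rng(seed)
    X = rng.binomial(4, 0.5, size=(n, m)).astype(float)
    if missing_rate:
        X[rng.random(X.shape) < missing_rate] = np.nan
    return pd.DataFrame(X, index=[f"S{i:02d}" for i in range(n)],
                        columns=[f"M{j}" for j in range(m)])


def _all_heights(node, acc=None):
    acc = [] if acc is None else acc
    if node.children:
        acc.append(node.height)
        for c in node.children:
            _all_heights(c, acc)
    return acc


class TestDistances:
    def test_identical_columns_zero(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"],
                         dtype=float)
        assert euclidean_distances(m).get("a", "b") == 0.0

    def test_single_locus_extremes(self):
        m = pd.DataFrame({"M1": [0.0, 4.0]}, index=["a", "b"])
        assert euclidean_distances(m).get("a", "b") == pytest.approx(4.0)

    def test_hand_example(self):
        m = pd.DataFrame([[0, 1, 2], [2, 1, 0]], index=["a", "b"],
                         dtype=float)
        assert euclidean_distances(m).get("a", "b") == pytest.approx(
            math.sqrt(8))

    def test_matches_brute_force_with_missing(self):
        m = _random_matrix(12, 20, seed=5, missing_rate=0.15)
        dm = euclidean_distances(m)
        for a, b in itertools.combinations(range(12), 2):
            d, shared = _brute_force_distance(m.iloc[a], m.iloc[b])
            got = dm.values[a, b]
            assert dm.shared[a, b] == shared
            if math.isnan(d):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(d)

    def test_metric_axioms_complete_data(self):
        m = _random_matrix(10, 15, seed=6)
        D = euclidean_distances(m).values
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        for i, j, k in itertools.permutations(range(10), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_scale_by_shared(self):
        m = pd.DataFrame({"M1": [0.0, 4.0], "M2": [0.0, np.nan]},
                         index=["a", "b"])
        plain = euclidean_distances(m).get("a", "b")
        scaled = euclidean_distances(m, scale_by_shared=True).get("a", "b")
        assert plain == pytest.approx(4.0)
        assert scaled == pytest.approx(4.0 * math.sqrt(2))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distances(pd.DataFrame({"M1": [1.0]}, index=["a"]))


class TestUpgma:
    def test_hand_computed_three_leaf_tree(self):
        """X=(0,0), Y=(0,2), Z=(4,4): first merge (X,Y) at height 1, root
        at mean(d(X,Z), d(Y,Z))/2."""
        m = pd.DataFrame([[0, 0], [0, 2], [4, 4]], index=["X", "Y", "Z"],
                         dtype=float)
        tree = upgma(euclidean_distances(m))
        d_xz, d_yz = math.sqrt(32), math.sqrt(20)
        assert tree.root.height == pytest.approx((d_xz + d_yz) / 4)
        inner = [c for c in tree.root.children if c.children][0]
        assert inner.height == pytest.approx(1.0)
        assert {leaf.label for leaf in inner.leaves()} == {"X", "Y"}

    def test_identical_samples_merge_at_zero(self):
        m = pd.DataFrame([[1, 2], [1, 2], [4, 0]], index=["a", "b", "c"],
                         dtype=float)
        tree = upgma(euclidean_distances(m))
        inner = [c for c in tree.root.children if c.children][0]
        assert inner.height == 0.0

    def test_matches_scipy_average_linkage(self):
        """Merge heights equal scipy's average-linkage heights (halved)
        on random 8-sample matrices."""
        for seed in (1, 2, 3):
            m = _random_matrix(8, 12, seed=seed)
            dm = euclidean_distances(m)
            tree = upgma(dm)
            Z = linkage(squareform(dm.values, checks=False), method="average")
            assert np.allclose(sorted(_all_heights(tree.root)),
                               sorted(Z[:, 2] / 2.0))

    def test_ultrametric_cophenetic(self):
        """For every leaf triple the two largest cophenetic distances
        are equal."""
        m = _random_matrix(8, 10, seed=9)
        tree = upgma(euclidean_distances(m))
        labels = tree.leaf_labels
        for a, b, c in itertools.combinations(labels, 3):
            ds = sorted([tree.cophenetic_distance(a, b),
                         tree.cophenetic_distance(a, c),
                         tree.cophenetic_distance(b, c)])
            assert ds[1] == pytest.approx(ds[2], abs=1e-9)

    def test_missing_distances_rejected(self):
        m = pd.DataFrame({"M1": [0.0, np.nan, 2.0],
                          "M2": [np.nan, 1.0, 2.0]},
                         index=["a", "b", "c"])
        with pytest.raises(ValueError, match="missing"):
            upgma(euclidean_distances(m))

    def test_deterministic_under_ties(self):
        m = pd.DataFrame([[0, 0], [0, 2], [2, 0], [2, 2]],
                         index=["d", "c", "b", "a"], dtype=float)
        t1 = upgma(euclidean_distances(m))
        t2 = upgma(euclidean_distances(m.iloc[::-1]))
        from tetrafinger.io_formats import write_newick
        assert write_newick(t1) == write_newick(t2)


class TestPca:
    def test_identical_samples_zero_scores(self):
        m = pd.DataFrame([[1, 2, 3]] * 4, index=list("abcd"), dtype=float)
        scores, evr = pca_scores(m, 2)
        assert np.allclose(scores.to_numpy(), 0.0)
        assert np.allclose(evr, 0.0)

    def test_two_clusters_separate_on_pc1(self):
        m = pd.DataFrame([[0, 0, 0]] * 5 + [[4, 4, 4]] * 5,
                         index=[f"s{i}" for i in range(10)], dtype=float)
        scores, evr = pca_scores(m, 2)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:5] * pc1[5:] < 0).all()
        assert evr[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition(self):
        """Scores equal an independent covariance eigendecomposition up
        to sign."""
        m = _random_matrix(20, 30, seed=14)
        scores, evr = pca_scores(m, 3)
        X = m.to_numpy() - m.to_numpy().mean(axis=0)
        vals, vecs = np.linalg.eigh(X.T @ X / (len(m) - 1))
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        expected = X @ vecs[:, :3]
        for j in range(3):
            got = scores.iloc[:, j].to_numpy()
            assert (np.allclose(got, expected[:, j], atol=1e-8)
                    or np.allclose(got, -expected[:, j], atol=1e-8))
        assert np.allclose(evr, vals[:3] / vals.sum())

    def test_mean_imputation_used_for_missing(self):
        m = _random_matrix(10, 6, seed=15, missing_rate=0.2)
        scores, _ = pca_scores(m, 2)
        assert np.isfinite(scores.to_numpy()).all()

    def test_too_few_samples_rejected(self):
        m = pd.DataFrame({"M1": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            pca_scores(m, 2)
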