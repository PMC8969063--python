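import itertools
import math

import numpy as np
import pytest

from grafttx.profiles import (
    dendrogram_to_newick,
    pca,
    ratio_profiles,
    train_som,
    ward_cluster,
)


class TestRatioProfiles:
    def test_closed_forms(self, make_condition_matrix):
        cond = make_condition_matrix(
            {
                "equal": (4.0, 4.0, 4.0),
                "triple": (2.0, 8.0, 8.0),
                "zero": (0.0, 0.0, 0.0),
            }
        )
        r = ratio_profiles(cond, "P_hybrida", pseudocount=1.0)
        assert r.data.loc["equal", ("interfamily", 3)] == 0.0
        assert r.data.loc["triple", ("interfamily", 3)] == pytest.approx(math.log2(3))
        assert r.data.loc["zero", ("interfamily", 7)] == 0.0

    def test_only_non_intact_conditions_emitted(self, make_condition_matrix):
        cond = make_condition_matrix({"g": (1.0, 2.0, 3.0)})
        r = ratio_profiles(cond, "P_hybrida")
        assert ("intact", 0) not in r.data.columns
        assert len(r.data.columns) == 6


def brute_force_ward(X):
    """Greedy Ward merges, recomputing cluster SSE from scratch each step."""
    X = np.asarray(X, dtype=float)

    def sse(members):
        pts = X[members]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters = {i: [i] for i in range(len(X))}
    heights = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            delta = sse(clusters[a] + clusters[b]) - sse(clusters[a]) - sse(clusters[b])
            if best is None or delta < best[0] - 1e-12:
                best = (delta, a, b)
        delta, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        heights.append(delta)
        next_id += 1
    return np.array(heights)


class TestWard:
    def test_identical_pair_merges_first_at_zero(self):
        d = ward_cluster(np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]]))
        a, b, h, _ = d.merges[0]
        assert {a, b} == {0, 2}
        assert h == 0.0

    def test_separated_pairs_merge_first(self):
        d = ward_cluster(np.array([[0.0], [1.0], [10.0], [11.0]]))
        first_two = [{m[0], m[1]} for m in d.merges[:2]]
        assert {0, 1} in first_two and {2, 3} in first_two

    def test_heights_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            X = rng.normal(size=(6, 5))
            mine = np.array([m[2] for m in ward_cluster(X).merges])
            np.testing.assert_allclose(mine, brute_force_ward(X), atol=1e-8)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 4))
        heights = [m[2] for m in ward_cluster(X).merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_rejects_single_vector(self):
        with pytest.raises(ValueError):
            ward_cluster(np.array([[1.0, 2.0]]))

    def test_newick_serialization(self):
        d = ward_cluster(np.array([[0.0], [0.1], [5.0]]), labels=["a", "b", "c"])
        nwk = dendrogram_to_newick(d)
        assert nwk.endswith(";") and "a" in nwk and "c" in nwk


class TestPCA:
    def test_collinear_samples_rank_one(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        res = pca(X)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_identical_samples_zero_fractions(self):
        X = np.ones((4, 3)) * 2.5
        res = pca(X)
        assert np.all(res.variance_fractions == 0)

    def test_scores_match_eigendecomposition(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 4))
        res = pca(X)
        eigval, eigvec = np.linalg.eigh(np.cov(X.T))
        order = np.argsort(eigval)[::-1]
        oracle = (X - X.mean(axis=0)) @ eigvec[:, order]
        for i in range(res.scores.shape[1]):
            mine = res.scores.to_numpy()[:, i]
            assert np.allclose(mine, oracle[:, i], atol=1e-8) or np.allclose(
                mine, -oracle[:, i], atol=1e-8
            )

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        assert pca(X).variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)

    def test_components_orthonormal(self):
        rng = np.random.default_rng(5)
        res = pca(rng.normal(size=(7, 5)))
        G = res.components @ res.components.T
        np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-10)


class TestSOM:
    def test_1x1_grid_is_global_mean(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        som = train_som(X, grid=(1, 1), epochs=1, seed=0)
        np.testing.assert_allclose(som.codebooks[0], X.mean(axis=0))

    def test_two_clusters_find_cluster_means(self):
        rng = np.random.default_rng(0)
        A = rng.normal(0, 0.1, size=(30, 2))
        B = rng.normal(5, 0.1, size=(30, 2))
        som = train_som(np.vstack([A, B]), grid=(1, 2), epochs=30, seed=0)
        books = som.codebooks[np.argsort(som.codebooks[:, 0])]
        np.testing.assert_allclose(books[0], A.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(books[1], B.mean(axis=0), atol=1e-6)

    def test_quantization_error_non_increasing(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 6))
        som = train_som(X, grid=(4, 4), epochs=40, seed=7)
        assert np.all(np.diff(som.qe_trace) <= 0 + 1e-12)
        assert len(som.qe_trace) == 40

    def test_every_profile_assigned_once(self):
        X = np.random.default_rng(1).normal(size=(25, 4))
        som = train_som(X, grid=(3, 3), epochs=10, seed=1)
        assert som.assignments.shape == (25,)
        assert som.assignments.min() >= 0 and som.assignments.max() < 9

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(2).normal(size=(30, 5))
        a = train_som(X, grid=(2, 3), epochs=15, seed=9)
        b = train_som(X, grid=(2, 3), epochs=15, seed=9)
        assert np.array_equal(a.codebooks, b.codebooks)
        assert np.array_equal(a.assignments, b.assignments)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_som(np.empty((0, 3)), grid=(2, 2), epochs=5, seed=0)
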