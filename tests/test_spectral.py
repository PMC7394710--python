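"""The clustering engine: RBF kernel, normalized Laplacian, embedding, k-means."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import planted_matrix
from morphodelim.spectral import (
    KernelConfig,
    SimilarityMatrix,
    canonicalize_labels,
    kmeans_partition,
    normalized_laplacian,
    rbf_similarity,
    spectral_cluster,
    spectral_embed,
)
from morphodelim.validation import nmi


def _block_similarity(sizes, within=1.0):
    """Hand-built block-diagonal similarity: disconnected cliques."""
    n = sum(sizes)
    S = np.zeros((n, n))
    start = 0
    for s in sizes:
        S[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(values=S, gamma=1.0)


class TestRBFKernel:
    def test_zero_distance_gives_unit_similarity(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 0.0]])
        S = rbf_similarity(X - X.mean(0), KernelConfig(gamma=0.5))
        assert S.values[0, 1] == pytest.approx(1.0)

    def test_scalar_kernel_value(self):
        """gamma=0.4, d=16, squared distance 16 -> exp(-0.4)."""
        X = np.vstack([np.full(16, -0.5), np.full(16, 0.5)])
        S = rbf_similarity(X, KernelConfig(gamma=0.4))
        assert S.values[0, 1] == pytest.approx(np.exp(-0.4), abs=1e-12)

    def test_doubling_gamma_squares_off_diagonals(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        X -= X.mean(0)
        S1 = rbf_similarity(X, KernelConfig(gamma=0.3)).values
        S2 = rbf_similarity(X, KernelConfig(gamma=0.6)).values
        np.testing.assert_allclose(S2, S1**2, atol=1e-12)

    def test_exponent_scale_variants(self):
        X = np.vstack([np.full(4, -0.5), np.full(4, 0.5)])  # squared distance 4, d=4
        g = 0.7
        assert rbf_similarity(X, KernelConfig(g, "divide")).values[0, 1] == pytest.approx(np.exp(-g))
        assert rbf_similarity(X, KernelConfig(g, "none")).values[0, 1] == pytest.approx(np.exp(-4 * g))
        assert rbf_similarity(X, KernelConfig(g, "multiply")).values[0, 1] == pytest.approx(np.exp(-16 * g))

    def test_gamma_must_be_positive(self):
        with pytest.raises(ValueError):
            KernelConfig(gamma=0.0)

    @given(st.floats(0.05, 2.0), st.floats(1.1, 4.0), st.integers(0, 100))
    def test_off_diagonal_decreasing_in_gamma_and_distance(self, gamma, factor, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 3))
        X -= X.mean(0)
        off = ~np.eye(5, dtype=bool)
        base = rbf_similarity(X, KernelConfig(gamma)).values
        sharper = rbf_similarity(X, KernelConfig(gamma * factor)).values
        spread = rbf_similarity(X * factor - (X * factor).mean(0), KernelConfig(gamma)).values
        assert np.all(sharper[off] < base[off])
        assert np.all(spread[off] < base[off])

    def test_unstandardized_input_warns(self):
        X = np.full((3, 2), 5.0) + np.arange(6).reshape(3, 2)
        with pytest.warns(UserWarning, match="standardized"):
            rbf_similarity(X, KernelConfig(gamma=0.5))


class TestSimilarityMatrixInvariants:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix(values=np.array([[1.0, 0.5], [0.4, 1.0]]), gamma=1.0)

    def test_bad_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            SimilarityMatrix(values=np.array([[0.9, 0.5], [0.5, 1.0]]), gamma=1.0)


class TestNormalizedLaplacian:
    def test_two_point_hand_example(self):
        S = SimilarityMatrix(values=np.array([[1.0, 1.0], [1.0, 1.0]]), gamma=1.0)
        bundle = normalized_laplacian(S)
        np.testing.assert_allclose(bundle.laplacian, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-15)
        np.testing.assert_allclose(np.linalg.eigvalsh(bundle.laplacian), [0.0, 1.0], atol=1e-12)

    def test_block_diagonal_zero_multiplicity(self):
        for sizes in [(2, 2), (3, 4, 2), (2, 2, 2, 3)]:
            bundle = normalized_laplacian(_block_similarity(sizes))
            w = np.linalg.eigvalsh(bundle.laplacian)
            assert np.sum(np.abs(w) <= 1e-8) == len(sizes)

    def test_eigenvalue_range_for_random_similarities(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X = rng.normal(size=(12, 4))
            S = rbf_similarity(X - X.mean(0), KernelConfig(gamma=float(rng.uniform(0.05, 3.0))))
            w = np.linalg.eigvalsh(normalized_laplacian(S).laplacian)
            assert w.min() >= -1e-10 and w.max() <= 2 + 1e-10

    def test_reconstruction_matches(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 3))
        S = rbf_similarity(X - X.mean(0), KernelConfig(gamma=0.8))
        bundle = normalized_laplacian(S)
        inv_sqrt = 1.0 / np.sqrt(bundle.degrees)
        rebuilt = np.eye(8) - inv_sqrt[:, None] * S.values * inv_sqrt[None, :]
        np.testing.assert_allclose(bundle.laplacian, (rebuilt + rebuilt.T) / 2, atol=1e-12)

    def test_zero_degree_rejected(self):
        # unit self-similarity makes a zero row sum unreachable through the
        # validated constructor, so mutate after construction to hit the guard
        sim = SimilarityMatrix(values=np.eye(3), gamma=1.0)
        sim.values[0, 0] = 0.0
        with pytest.raises(ValueError, match="isolated"):
            normalized_laplacian(sim)


class TestSpectralEmbedding:
    def test_full_basis_at_K_equals_N(self):
        bundle = normalized_laplacian(_block_similarity((3, 3)))
        emb = spectral_embed(bundle, 6)
        assert emb.coordinates.shape == (6, 6)
        assert len(emb.eigenvalues) == 6

    def test_rows_unit_norm(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        S = rbf_similarity(X - X.mean(0), KernelConfig(gamma=0.5))
        emb = spectral_embed(normalized_laplacian(S), 3)
        np.testing.assert_allclose(np.linalg.norm(emb.coordinates, axis=1), 1.0, atol=1e-10)

    def test_disconnected_blocks_collapse_to_two_points(self):
        bundle = normalized_laplacian(_block_similarity((2, 2)))
        emb = spectral_embed(bundle, 2)
        a, b = emb.coordinates[:2], emb.coordinates[2:]
        np.testing.assert_allclose(a[0], a[1], atol=1e-8)
        np.testing.assert_allclose(b[0], b[1], atol=1e-8)
        assert np.linalg.norm(a[0] - b[0]) > 0.5

    def test_K_out_of_range(self):
        bundle = normalized_laplacian(_block_similarity((2, 2)))
        with pytest.raises(ValueError):
            spectral_embed(bundle, 0)
        with pytest.raises(ValueError):
            spectral_embed(bundle, 5)


class TestKMeans:
    def test_planted_bipartition_matches_exhaustive_oracle(self):
        """At N=8, K=2 the selected objective equals the best of all 2^7-1 bipartitions."""
        for seed in range(5):
            pts = np.random.default_rng(seed).normal(size=(8, 2))
            best = np.inf
            for mask in range(1, 2**7):
                g = np.array([(mask >> i) & 1 for i in range(8)])
                obj = sum(
                    float(((pts[g == lab] - pts[g == lab].mean(0)) ** 2).sum())
                    for lab in (0, 1)
                    if np.any(g == lab)
                )
                best = min(best, obj)
            a = kmeans_partition(pts, 2, restarts=50, seed=seed)
            assert a.kmeans_objective == pytest.approx(best, abs=1e-9)

    def test_single_cluster_objective_is_total_ss(self):
        pts = np.random.default_rng(1).normal(size=(9, 3))
        a = kmeans_partition(pts, 1, restarts=5, seed=0)
        assert np.all(a.labels == 0)
        assert a.kmeans_objective == pytest.approx(float(((pts - pts.mean(0)) ** 2).sum()))

    def test_saturated_clustering_has_zero_objective(self):
        pts = np.arange(12, dtype=float).reshape(6, 2)
        a = kmeans_partition(pts, 6, restarts=5, seed=0)
        assert a.kmeans_objective == pytest.approx(0.0, abs=1e-12)
        assert len(set(a.labels.tolist())) == 6

    def test_K_exceeding_distinct_points_is_error(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="distinct"):
            kmeans_partition(pts, 3, restarts=2, seed=0)

    def test_more_restarts_never_worse(self):
        pts = np.random.default_rng(4).normal(size=(30, 2))
        objs = [kmeans_partition(pts, 4, restarts=r, seed=7).kmeans_objective for r in (1, 5, 20, 50)]
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_labels_canonicalized_by_first_occurrence(self):
        assert canonicalize_labels(np.array([2, 2, 0, 1, 0])).tolist() == [0, 0, 1, 2, 1]
        pts = np.vstack([np.zeros((3, 2)), np.ones((3, 2)) * 10])
        a = kmeans_partition(pts + np.random.default_rng(0).normal(scale=0.01, size=pts.shape), 2, seed=0)
        assert a.labels[0] == 0


class TestSpectralCluster:
    def test_planted_three_taxa_recovered_exactly(self):
        matrix, labels = planted_matrix(seed=11, centroid_separation=10.0)
        a = spectral_cluster(matrix, gamma=0.4, K=3, restarts=20, seed=1)
        assert nmi(a.labels, labels) == pytest.approx(1.0)

    def test_single_cluster_is_valid(self):
        matrix, _ = planted_matrix(seed=11)
        a = spectral_cluster(matrix, gamma=0.4, K=1, restarts=5, seed=0)
        assert np.all(a.labels == 0)

    def test_deterministic_given_seed(self):
        matrix, _ = planted_matrix(seed=12, centroid_separation=1.0)
        a = spectral_cluster(matrix, gamma=0.4, K=4, restarts=10, seed=5)
        b = spectral_cluster(matrix, gamma=0.4, K=4, restarts=10, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.kmeans_objective == b.kmeans_objective

    def test_block_partition_equals_blocks(self):
        """For block-diagonal similarity with c blocks and K=c the partition is the blocks."""
        sizes = (3, 4, 5)
        bundle = normalized_laplacian(_block_similarity(sizes))
        emb = spectral_embed(bundle, 3)
        a = kmeans_partition(emb, 3, restarts=10, seed=0)
        expected = np.repeat(np.arange(3), sizes)
        np.testing.assert_array_equal(a.labels, canonicalize_labels(expected))
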