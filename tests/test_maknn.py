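"""Approximate nearest-anchor search: index construction and queries."""

import numpy as np
import pytest

from secuer import (
    build_anchor_index,
    gaussian_mixture,
    query_k_nearest_anchors,
    select_anchors,
)
from secuer.anchors import AnchorSet
from secuer.maknn import pairwise_distances

from conftest import brute_force_knn


def _random_anchorset(p, d, seed=0):
    rng = np.random.default_rng(seed)
    return AnchorSet(rng.random((p, d)), p, p, seed)


class TestBuildAnchorIndex:
    @pytest.mark.parametrize(
        "p,expected_o", [(1000, 32), (100, 10), (20, 4), (4, 2)]
    )
    def test_anchor_cluster_count_is_root_p(self, p, expected_o):
        idx = build_anchor_index(_random_anchorset(p, 3), k=2)
        assert idx.o == expected_o

    def test_k_prime_is_ten_k(self):
        idx = build_anchor_index(_random_anchorset(1000, 3), k=7)
        assert idx.k_prime == 70

    def test_k_prime_clamped_to_p_minus_one(self):
        idx = build_anchor_index(_random_anchorset(20, 3), k=7)
        assert idx.k_prime == 19

    def test_neighbor_table_rows_are_distinct_and_self_free(self):
        idx = build_anchor_index(_random_anchorset(50, 4, seed=1), k=3)
        for j, row in enumerate(idx.anchor_knn):
            assert j not in row
            assert len(set(row)) == idx.k_prime


class TestQuery:
    def test_cell_on_anchor_gets_that_anchor_first(self):
        anchors = _random_anchorset(30, 5, seed=2)
        idx = build_anchor_index(anchors, k=3)
        X = np.vstack([anchors.coords[17], anchors.coords[4]])
        nbr = query_k_nearest_anchors(X, idx, anchors, k=3)
        assert nbr.anchor_idx[0, 0] == 17 and nbr.dist[0, 0] == 0.0
        assert nbr.anchor_idx[1, 0] == 4 and nbr.dist[1, 0] == 0.0

    def test_full_candidate_set_equals_brute_force_exactly(self):
        # k' = p - 1 makes the candidate set exhaustive
        ds = gaussian_mixture(400, 6, 3, 8.0, seed=3)
        X = ds.matrix.dense()
        anchors = select_anchors(X, p=40, seed=0)
        idx = build_anchor_index(anchors, k=5, k_prime=39)
        nbr = query_k_nearest_anchors(X, idx, anchors, k=5)
        oracle_idx, oracle_dist = brute_force_knn(X, anchors.coords, 5)
        np.testing.assert_array_equal(nbr.anchor_idx, oracle_idx)
        np.testing.assert_allclose(nbr.dist, oracle_dist, atol=1e-12)

    def test_p_not_larger_than_k_degenerates_to_brute_force(self):
        anchors = _random_anchorset(4, 3, seed=4)
        idx = build_anchor_index(anchors, k=2)
        X = np.random.default_rng(5).random((20, 3))
        nbr = query_k_nearest_anchors(X, idx, anchors, k=6)
        oracle_idx, oracle_dist = brute_force_knn(X, anchors.coords, 4)
        np.testing.assert_array_equal(nbr.anchor_idx, oracle_idx)
        np.testing.assert_allclose(nbr.dist, oracle_dist, atol=1e-12)

    @pytest.mark.parametrize("metric", ["euclidean", "cosine"])
    def test_returned_distances_match_recomputation(self, metric):
        ds = gaussian_mixture(300, 5, 2, 6.0, seed=6)
        X = np.abs(ds.matrix.dense()) + 0.1  # keep away from zero norm
        anchors = select_anchors(X, p=30, seed=0)
        idx = build_anchor_index(anchors, k=4, metric=metric)
        nbr = query_k_nearest_anchors(X, idx, anchors, k=4)
        for i in range(0, X.shape[0], 37):
            D = pairwise_distances(
                X[i : i + 1], anchors.coords[nbr.anchor_idx[i]], metric
            ).ravel()
            np.testing.assert_allclose(nbr.dist[i], D, atol=1e-12)

    def test_high_recall_on_mixture_fixture(self):
        ds = gaussian_mixture(2000, 10, 4, 10.0, seed=7)
        X = ds.matrix.dense()
        anchors = select_anchors(X, p=150, seed=0)
        idx = build_anchor_index(anchors, k=7)
        nbr = query_k_nearest_anchors(X, idx, anchors, k=7)
        oracle_idx, _ = brute_force_knn(X, anchors.coords, 7)
        recall = np.mean(
            [
                len(set(a) & set(b)) / 7.0
                for a, b in zip(nbr.anchor_idx, oracle_idx)
            ]
        )
        assert recall >= 0.90

    def test_distance_evaluation_budget_respected(self):
        # per cell at most o + (max anchor-cluster size) + k' + 1 distances
        ds = gaussian_mixture(1000, 8, 3, 10.0, seed=8)
        X = ds.matrix.dense()
        anchors = select_anchors(X, p=100, seed=0)
        idx = build_anchor_index(anchors, k=5)
        nbr = query_k_nearest_anchors(X, idx, anchors, k=5)
        max_cluster = np.bincount(idx.anchor_cluster_of, minlength=idx.o).max()
        per_cell_cap = idx.o + max_cluster + idx.k_prime + 1
        assert nbr.n_dist_evals <= X.shape[0] * per_cell_cap

    def test_k_larger_than_candidate_set_raises(self):
        anchors = _random_anchorset(50, 3, seed=9)
        idx = build_anchor_index(anchors, k=1, k_prime=2)
        with pytest.raises(ValueError, match="candidate"):
            query_k_nearest_anchors(np.random.random((10, 3)), idx, anchors, k=5)

    def test_dimension_mismatch_raises(self):
        anchors = _random_anchorset(20, 3)
        idx = build_anchor_index(anchors, k=2)
        with pytest.raises(ValueError, match="features"):
            query_k_nearest_anchors(np.random.random((5, 4)), idx, anchors, k=2)


class TestCosineDistance:
    def test_zero_norm_vector_is_at_distance_one_from_everything(self):
        A = np.array([[0.0, 0.0], [1.0, 0.0]])
        B = np.array([[0.0, 1.0], [3.0, 0.0]])
        D = pairwise_distances(A, B, "cosine")
        np.testing.assert_allclose(D[0], [1.0, 1.0])
        np.testing.assert_allclose(D[1], [1.0, 0.0], atol=1e-12)

    def test_cosine_matches_definition(self):
        rng = np.random.default_rng(10)
        A, B = rng.random((4, 6)), rng.random((3, 6))
        D = pairwise_distances(A, B, "cosine")
        for i in range(4):
            for j in range(3):
                expect = 1 - A[i] @ B[j] / (
                    np.linalg.norm(A[i]) * np.linalg.norm(B[j])
                )
                assert D[i, j] == pytest.approx(expect, abs=1e-12)
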