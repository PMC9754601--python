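"""Transfer-cut reduction, lifting, and the full clustering pipeline."""

import numpy as np
import pytest
import scipy.sparse as sp

from secuer import (
    BipartiteAffinity,
    ari,
    gaussian_mixture,
    reduced_problem,
    row_normalize,
    secuer,
    tcut_embedding,
)

from conftest import dense_bipartite_eigenproblem, make_affinity


def _aff_from_dense(B):
    B = sp.csr_matrix(np.asarray(B, float))
    k = int(np.diff(B.indptr).max())
    return BipartiteAffinity(B, sigma=None, k=k, metric="euclidean")


class TestReducedProblem:
    def test_wp_matches_dense_product_oracle(self):
        rng = np.random.default_rng(0)
        B = rng.random((50, 8)) * (rng.random((50, 8)) < 0.4)
        B[B.sum(axis=1) == 0, 0] = 0.5  # every cell connected
        graph = reduced_problem(_aff_from_dense(B))
        Bd = graph.B.toarray()
        oracle = Bd.T @ np.diag(1.0 / Bd.sum(axis=1)) @ Bd
        np.testing.assert_allclose(graph.W_p.toarray(), oracle, atol=1e-12)
        # D_p identity: diag(W_p 1) equals the column sums of B
        np.testing.assert_allclose(graph.d_p, Bd.sum(axis=0), atol=1e-12)

    def test_transition_matrix_is_row_stochastic(self):
        ds = gaussian_mixture(200, 5, 2, 8.0, seed=1)
        _, _, _, aff = make_affinity(ds.matrix.dense(), p=20, k=4)
        graph = reduced_problem(aff)
        np.testing.assert_allclose(
            np.asarray(graph.P.sum(axis=1)).ravel(), 1.0, atol=1e-10
        )

    def test_disjoint_column_blocks_give_block_diagonal_wp(self):
        B = np.zeros((6, 4))
        B[:3, :2] = [[1, 2], [2, 1], [1, 1]]
        B[3:, 2:] = [[3, 1], [1, 3], [2, 2]]
        Wp = reduced_problem(_aff_from_dense(B)).W_p.toarray()
        assert np.all(Wp[:2, 2:] == 0) and np.all(Wp[2:, :2] == 0)
        assert Wp[0, 1] > 0 and Wp[2, 3] > 0

    def test_zero_degree_anchor_dropped_with_warning(self):
        B = np.array([[1.0, 0.0, 2.0], [2.0, 0.0, 1.0], [1.0, 0.0, 1.0]])
        with pytest.warns(UserWarning, match="zero-degree"):
            graph = reduced_problem(_aff_from_dense(B))
        assert graph.W_p.shape == (2, 2)
        np.testing.assert_array_equal(graph.kept_anchors, [0, 2])


class TestTcutEmbedding:
    def test_two_components_give_two_zero_eigenvalues_and_two_rows(self):
        # affinity graph with exactly 2 connected components
        ds1 = gaussian_mixture(100, 4, 1, 1.0, seed=2).matrix.dense()
        ds2 = gaussian_mixture(100, 4, 1, 1.0, seed=3).matrix.dense() + 50.0
        X = np.vstack([ds1, ds2])
        _, _, _, aff = make_affinity(X, p=16, k=3, seed=0)
        # oracle: component count from graph traversal of the bipartite graph
        n, p = aff.B.shape
        W = sp.bmat([[None, aff.B], [aff.B.T, None]])
        n_comp, _ = sp.csgraph.connected_components(W, directed=False)
        assert n_comp == 2
        emb = tcut_embedding(aff, K=2)
        assert np.all(emb.lambdas < 1e-8)
        Tn = row_normalize(emb.T)
        uniq = np.unique(np.round(Tn, 6), axis=0)
        assert uniq.shape[0] == 2

    def test_gamma_lambda_identity_holds(self):
        ds = gaussian_mixture(300, 6, 3, 8.0, seed=4)
        _, _, _, aff = make_affinity(ds.matrix.dense(), p=30, k=4)
        emb = tcut_embedding(aff, K=6)
        np.testing.assert_allclose(
            emb.gammas * (2 - emb.gammas), emb.lambdas, atol=1e-8
        )

    def test_lift_matches_dense_full_eigenproblem(self):
        # the central equivalence: reduced p x p solve + lift reproduces the
        # cell block of the dense (N+p) generalized eigenproblem
        ds = gaussian_mixture(300, 6, 3, 8.0, seed=5)
        _, _, _, aff = make_affinity(ds.matrix.dense(), p=30, k=4)
        K = 5
        emb = tcut_embedding(aff, K)
        gammas_full, V_cells, _ = dense_bipartite_eigenproblem(aff.B, K)
        np.testing.assert_allclose(emb.gammas, gammas_full, atol=1e-8)
        # compare per simple eigenpair up to sign/scale via |cosine|
        for e in range(K):
            gap = min(
                abs(gammas_full[e] - gammas_full[e - 1]) if e > 0 else 1.0,
                abs(gammas_full[e + 1] - gammas_full[e]) if e < K - 1 else 1.0,
            )
            if gap < 1e-6:
                continue  # degenerate pair: eigenvector not unique
            u, v = emb.T[:, e], V_cells[:, e]
            cos = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
            assert cos >= 1 - 1e-6

    def test_k_beyond_anchor_count_raises(self):
        ds = gaussian_mixture(100, 4, 2, 8.0, seed=6)
        _, _, _, aff = make_affinity(ds.matrix.dense(), p=10, k=3)
        with pytest.raises(ValueError, match="eigenpairs"):
            tcut_embedding(aff, K=11)


class TestSecuerPipeline:
    def test_recovers_well_separated_blobs(self):
        ds = gaussian_mixture(900, 10, 3, 10.0, seed=7)
        res = secuer(ds.matrix, p=90, k=7, fixed_K=3, seed=0)
        assert ari(res.labels, ds.labels) == 1.0

    def test_two_far_blobs_match_membership_up_to_permutation(self):
        ds = gaussian_mixture(400, 6, 2, 30.0, seed=8)
        res = secuer(ds.matrix, p=40, k=5, fixed_K=2, seed=0)
        assert ari(res.labels, ds.labels) == 1.0

    def test_deterministic_given_seed(self):
        ds = gaussian_mixture(400, 6, 3, 8.0, seed=9)
        r1 = secuer(ds.matrix, p=40, k=5, seed=11)
        r2 = secuer(ds.matrix, p=40, k=5, seed=11)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.n_clusters == r2.n_clusters

    def test_fixed_k_equal_to_n_raises(self):
        ds = gaussian_mixture(100, 4, 2, 8.0, seed=10)
        with pytest.raises(ValueError, match="n_clusters"):
            secuer(ds.matrix, p=20, k=3, fixed_K=100)

    def test_no_dense_cell_level_arrays(self):
        # memory contract: the only cell-sized artifacts are sparse B (N*k
        # entries) and the N x K embedding
        ds = gaussian_mixture(500, 8, 3, 10.0, seed=11)
        from secuer import SecuerClustering

        est = SecuerClustering(
            n_clusters=3, n_anchors=50, n_neighbors=5, random_state=0
        ).fit(ds.matrix)
        assert sp.issparse(est.affinity_.B)
        assert est.affinity_.B.nnz == 500 * 5
        assert est.embedding_.shape == (500, 3)
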