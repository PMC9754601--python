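"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
import scipy.linalg
import scipy.sparse as sp

from secuer import (
    build_anchor_index,
    compute_affinity,
    gaussian_mixture,
    query_k_nearest_anchors,
    select_anchors,
)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # sklearn emits convergence chatter for tiny k-means problems; tests
    # assert on results, not warnings, unless they opt in explicitly.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def make_affinity(X, p, k, seed=0, metric="euclidean", k_prime=None):
    """Run anchors -> index -> query -> affinity on raw coordinates."""
    anchors = select_anchors(X, p=p, seed=seed)
    index = build_anchor_index(anchors, k, metric=metric, seed=seed, k_prime=k_prime)
    nbr = query_k_nearest_anchors(X, index, anchors, k)
    return anchors, index, nbr, compute_affinity(nbr, n_anchors=p)


def dense_bipartite_eigenproblem(B, K):
    """Oracle: solve the full (N+p) generalized eigenproblem densely.

    Builds W = [[0, B], [B', 0]], L = D - W, and solves L v = gamma D v
    with a dense generalized symmetric eigensolver.  Returns the K
    smallest eigenvalues gamma and the corresponding eigenvectors split
    into cell and anchor blocks.
    """
    B = np.asarray(B.todense()) if sp.issparse(B) else np.asarray(B)
    n, p = B.shape
    W = np.zeros((n + p, n + p))
    W[:n, n:] = B
    W[n:, :n] = B.T
    D = np.diag(W.sum(axis=1))
    L = D - W
    gammas, V = scipy.linalg.eigh(L, D)
    return gammas[:K], V[:n, :K], V[n:, :K]


def brute_force_knn(X, coords, k, metric="euclidean"):
    """Oracle: exact k nearest anchors by full distance matrix."""
    from secuer.maknn import pairwise_distances

    D = pairwise_distances(X, coords, metric)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    return order, np.take_along_axis(D, order, axis=1)


@pytest.fixture(scope="session")
def blobs3():
    """3 well-separated Gaussian blobs, the workhorse fixture."""
    return gaussian_mixture(600, 8, 3, separation=12.0, seed=42)
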