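"""Transfer-cut partitioning of the cell-anchor bipartite graph.

Writing the (N+p) x (N+p) bipartite adjacency as W = [[0, B], [B', 0]],
spectral clustering would solve the generalized eigenproblem

    L v = gamma D v,        L = D - W                              (full)

which is intractable at single-cell scale.  Because the graph is bipartite
and heavily unbalanced (p << N), the transfer-cut reduction solves instead
the p x p problem on the anchor side,

    L_p z = lambda D_p z,   W_p = B' D_X^{-1} B,  L_p = D_p - W_p  (reduced)

whose eigenpairs map one-to-one onto the full problem's:

    gamma (2 - gamma) = lambda,   v = [xi; z],
    xi = P z / (1 - gamma),       P = D_X^{-1} B (row-stochastic).

The cell-side vectors xi, stacked as T and row-normalized, are the spectral
embedding that the final k-means consumes.  Nothing larger than N x k
(sparse) or N x K (dense) is ever materialized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .affinity import BipartiteAffinity

__all__ = [
    "SpectralEmbedding",
    "ClusteringResult",
    "ReducedGraph",
    "reduced_problem",
    "tcut_embedding",
    "reduced_eigenvalues",
    "row_normalize",
    "secuer",
]

#: Below this anchor count the reduced eigenproblem is always solved densely
#: (robustness over speed at toy scale).
DENSE_EIGEN_CUTOFF = 200
#: Dense retry bound when the iterative solver fails to converge.
DENSE_RETRY_CUTOFF = 2000


@dataclass
class ReducedGraph:
    """Auxiliary matrices of the reduced (anchor-side) eigenproblem."""

    B: sp.csr_matrix  # N x p, zero-degree anchors dropped
    d_x: np.ndarray  # cell degrees (row sums of B)
    P: sp.csr_matrix  # D_X^{-1} B, row-stochastic
    W_p: sp.csr_matrix  # B' D_X^{-1} B
    d_p: np.ndarray  # anchor degrees (diag of D_p)
    kept_anchors: np.ndarray  # original column indices that survived


@dataclass
class SpectralEmbedding:
    """Eigenpairs of the reduced problem and the lifted cell-side embedding."""

    lambdas: np.ndarray  # K ascending eigenvalues of the reduced problem
    gammas: np.ndarray  # 1 - sqrt(1 - lambda), eigenvalues of the full problem
    Z: np.ndarray  # p x K anchor-side eigenvectors
    T: np.ndarray  # N x K lifted cell-side vectors xi (unnormalized)
    graph: ReducedGraph


@dataclass
class ClusteringResult:
    """Final labels plus the parameter record needed to reproduce them."""

    labels: np.ndarray
    n_clusters: int
    seed: int | None = None
    params: dict[str, Any] = field(default_factory=dict)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size:
            present = np.unique(self.labels)
            if present.size < self.n_clusters:
                warnings.warn(
                    f"only {present.size} of {self.n_clusters} clusters are "
                    "occupied",
                    stacklevel=2,
                )


def reduced_problem(aff: BipartiteAffinity) -> ReducedGraph:
    """Form D_X, P, W_p and D_p as sparse products.

    Anchors nobody is connected to (all-zero columns of B) are dropped with
    a warning and the remaining columns re-indexed; cell rows are guaranteed
    nonzero upstream.  The full (N+p) adjacency is never materialized.
    """
    B = sp.csr_matrix(aff.B)
    col_deg = np.asarray(B.sum(axis=0)).ravel()
    kept = np.flatnonzero(col_deg > 0)
    if kept.size < B.shape[1]:
        warnings.warn(
            f"dropping {B.shape[1] - kept.size} zero-degree anchors",
            stacklevel=2,
        )
        B = sp.csr_matrix(B[:, kept])
    d_x = np.asarray(B.sum(axis=1)).ravel()
    if np.any(d_x <= 0):
        raise ValueError("every cell must connect to at least one anchor")
    inv_dx = sp.diags(1.0 / d_x)
    P = sp.csr_matrix(inv_dx @ B)
    W_p = sp.csr_matrix(B.T @ inv_dx @ B)
    d_p = np.asarray(W_p.sum(axis=1)).ravel()
    return ReducedGraph(B, d_x, P, W_p, d_p, kept)


def _reduced_spectrum(graph: ReducedGraph, m: int) -> tuple[np.ndarray, np.ndarray]:
    """The m smallest eigenpairs of L_p z = lambda D_p z.

    Solved through the symmetric form D_p^{-1/2} L_p D_p^{-1/2}; eigenvalues
    ascend, eigenvectors are returned already de-scaled (columns are z).
    """
    W_p, d_p = graph.W_p, graph.d_p
    p = W_p.shape[0]
    if not 1 <= m <= p:
        raise ValueError(f"cannot extract {m} eigenpairs from a {p}-anchor graph")
    s = 1.0 / np.sqrt(d_p)
    S = sp.diags(s)
    A = S @ W_p @ S  # eigenvalues mu of A give lambda = 1 - mu
    if p <= DENSE_EIGEN_CUTOFF or m >= p - 1:
        mu, Y = scipy.linalg.eigh(np.asarray(A.todense()))
        mu, Y = mu[::-1][:m], Y[:, ::-1][:, :m]
    else:
        try:
            mu, Y = spla.eigsh(A, k=m, which="LA", v0=np.full(p, 1.0 / np.sqrt(p)))
            order = np.argsort(mu)[::-1]
            mu, Y = mu[order], Y[:, order]
        except spla.ArpackNoConvergence:
            if p > DENSE_RETRY_CUTOFF:
                raise
            mu, Y = scipy.linalg.eigh(np.asarray(A.todense()))
            mu, Y = mu[::-1][:m], Y[:, ::-1][:, :m]
    lambdas = 1.0 - mu  # ascending
    lambdas = np.maximum(lambdas, 0.0)  # clip fp noise below zero
    Z = s[:, None] * Y
    return lambdas, Z


def reduced_eigenvalues(aff: BipartiteAffinity, m: int = 50) -> np.ndarray:
    """The ``min(p, m)`` smallest eigenvalues of the reduced problem."""
    graph = reduced_problem(aff)
    m = min(m, graph.W_p.shape[0])
    lam, _ = _reduced_spectrum(graph, m)
    return lam


def tcut_embedding(aff: BipartiteAffinity, K: int) -> SpectralEmbedding:
    """Solve the reduced problem for K eigenpairs and lift to the cells.

    Eigenvalues numerically >= 1 (gamma would hit 1) are clipped to
    1 - 1e-12 with a warning; the corresponding lift is still defined.
    """
    graph = reduced_problem(aff)
    lambdas, Z = _reduced_spectrum(graph, K)
    if np.any(lambdas >= 1.0):
        warnings.warn(
            "reduced eigenvalues >= 1 clipped; the affinity graph is close "
            "to bipartite-degenerate",
            stacklevel=2,
        )
        lambdas = np.minimum(lambdas, 1.0 - 1e-12)
    gammas = 1.0 - np.sqrt(1.0 - lambdas)
    T = (graph.P @ Z) / (1.0 - gammas)[None, :]
    return SpectralEmbedding(lambdas, gammas, Z, T, graph)


def row_normalize(T: np.ndarray) -> np.ndarray:
    """L2-normalize rows; all-zero rows are left at zero."""
    norms = np.linalg.norm(T, axis=1)
    out = T.copy()
    nz = norms > 0
    out[nz] /= norms[nz, None]
    return out


def secuer(
    X,
    p: int = 1000,
    k: int = 7,
    subsample_size: int | None = None,
    fixed_K: int | None = None,
    k_method: str = "anchor_graph",
    metric: str = "euclidean",
    resolution: float = 1.0,
    alpha: int = 4,
    seed: int = 0,
) -> ClusteringResult:
    """Run the full anchor-based spectral clustering pipeline.

    Thin functional wrapper over :class:`secuer.cluster.SecuerClustering`;
    see that class for the parameter semantics.
    """
    from .cluster import SecuerClustering  # deferred: avoids a cycle

    est = SecuerClustering(
        n_clusters=fixed_K,
        n_anchors=p,
        n_neighbors=k,
        subsample_size=subsample_size,
        k_method=k_method,
        metric=metric,
        resolution=resolution,
        alpha=alpha,
        random_state=seed,
    )
    est.fit(X)
    return est.result_
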