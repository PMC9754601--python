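"""Scikit-learn style estimators for anchor-based spectral clustering.

:class:`SecuerClustering` is the single-run pipeline: anchor selection,
approximate nearest-anchor search, locally scaled affinities, optional
cluster-number estimation, transfer-cut embedding and a final k-means.
:class:`SecuerConsensusClustering` aggregates several such runs through a
cell-cluster incidence graph partitioned with the same machinery.  Both
follow the sklearn estimator contract (``get_params``/``set_params``,
``fit``/``fit_predict``, trailing-underscore fitted attributes) and so
compose with pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_random_state, validate_data

from .affinity import compute_affinity
from .anchors import clamp_anchor_count, select_anchors
from .io import ExpressionMatrix
from .kestimate import (
    EigengapConfig,
    estimate_k_anchor_graph,
    estimate_k_eigengap_from_affinity,
)
from .maknn import build_anchor_index, query_k_nearest_anchors
from .spectral import ClusteringResult, row_normalize, tcut_embedding

__all__ = ["SecuerClustering", "SecuerConsensusClustering"]


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible 31-bit sub-seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def _resolve_input(X):
    """Split an input into (values, cell_ids) accepting ExpressionMatrix."""
    if isinstance(X, ExpressionMatrix):
        return X.values, list(X.cell_ids)
    return X, []


def _assign_zero_rows(labels, Tn, nbr, B):
    """Give cells with an all-zero embedding row their anchor's majority label.

    Zero rows only arise from numerical degeneracy; the cluster of the
    cell's nearest anchor -- the majority label among cells attached to
    that anchor -- is the natural fallback.
    """
    zero_rows = np.flatnonzero(np.linalg.norm(Tn, axis=1) == 0)
    if zero_rows.size == 0:
        return labels
    Bc = sp.csc_matrix(B)
    for i in zero_rows:
        j = int(nbr.nearest_anchor[i])
        attached = Bc[:, j].indices
        attached = attached[attached != i]
        if attached.size:
            vals, cnt = np.unique(labels[attached], return_counts=True)
            labels[i] = vals[np.argmax(cnt)]
    return labels


class SecuerClustering(ClusterMixin, BaseEstimator):
    """Anchor-based bipartite-graph spectral clustering.

    Parameters
    ----------
    n_clusters : int or None
        Fixed number of clusters K.  ``None`` (default) estimates K from
        the data with ``k_method``.
    n_anchors : int, default 1000
        Number of anchors p.  Clamped to ``n_cells // 2`` with a warning
        on inputs too small for the requested value.
    n_neighbors : int, default 7
        Nearest anchors per cell, k.
    subsample_size : int or None
        Cells fed to anchor-selecting k-means; ``None`` means
        ``10 * n_anchors`` capped at the dataset size.
    k_method : {"anchor_graph", "eigengap"}
        Cluster-number estimator used when ``n_clusters`` is None.
    metric : {"euclidean", "cosine"}
        Distance used for neighbor search and kernel bandwidths.
    resolution : float, default 1.0
        Louvain resolution for the anchor-graph estimator.
    alpha : int, default 4
        Gap-threshold rank for the eigengap estimator.
    random_state : int, RandomState or None
        Seeds every stochastic stage; identical input and seed give
        identical labels.

    Attributes
    ----------
    labels_ : ndarray of shape (n_cells,)
        Cluster label of each cell.
    n_clusters_ : int
        Number of clusters used (estimated or fixed).
    anchors_ : AnchorSet
    affinity_ : BipartiteAffinity
    embedding_ : ndarray of shape (n_cells, n_clusters_)
        Row-normalized spectral embedding the final k-means clustered.
    result_ : ClusteringResult
        Labels plus the full parameter record.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        n_anchors: int = 1000,
        n_neighbors: int = 7,
        subsample_size: int | None = None,
        k_method: str = "anchor_graph",
        metric: str = "euclidean",
        resolution: float = 1.0,
        alpha: int = 4,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.n_anchors = n_anchors
        self.n_neighbors = n_neighbors
        self.subsample_size = subsample_size
        self.k_method = k_method
        self.metric = metric
        self.resolution = resolution
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y=None):
        values, cell_ids = _resolve_input(X)
        values = validate_data(self, values, accept_sparse="csr", dtype=np.float64)
        n = values.shape[0]
        if n < 4:
            raise ValueError("need at least 4 cells")
        if self.k_method not in ("anchor_graph", "eigengap"):
            raise ValueError(f"unknown k_method {self.k_method!r}")
        rs = check_random_state(self.random_state)
        seed = int(rs.randint(2**31))
        s_anchor, s_index, s_louvain, s_kmeans = _sub_seeds(seed, 4)

        p = clamp_anchor_count(int(self.n_anchors), n)
        if self.n_clusters is not None:
            if not 1 <= self.n_clusters < n:
                raise ValueError(
                    f"n_clusters={self.n_clusters} must lie in [1, n_cells)"
                )
            if self.n_clusters > p:
                raise ValueError(
                    f"n_clusters={self.n_clusters} exceeds anchor count {p}"
                )

        anchors = select_anchors(values, p, self.subsample_size, s_anchor)
        index = build_anchor_index(
            anchors, self.n_neighbors, self.metric, s_index
        )
        nbr = query_k_nearest_anchors(values, index, anchors, self.n_neighbors)
        aff = compute_affinity(nbr, n_anchors=p)

        if self.n_clusters is not None:
            K = int(self.n_clusters)
        elif self.k_method == "anchor_graph":
            K = estimate_k_anchor_graph(aff, self.resolution, s_louvain)
        else:
            K = estimate_k_eigengap_from_affinity(
                aff, EigengapConfig(alpha=self.alpha)
            )
        K = max(1, min(K, p, n - 1))

        emb = tcut_embedding(aff, K)
        Tn = row_normalize(emb.T)
        km = KMeans(n_clusters=K, init="k-means++", n_init=10, random_state=s_kmeans)
        labels = km.fit_predict(Tn)
        labels = _assign_zero_rows(labels, Tn, nbr, aff.B)

        self.anchors_ = anchors
        self.neighbor_assignment_ = nbr
        self.affinity_ = aff
        self.spectral_ = emb
        self.embedding_ = Tn
        self.labels_ = labels
        self.n_clusters_ = K
        self.result_ = ClusteringResult(
            labels,
            K,
            seed=seed,
            params={
                "n_anchors": p,
                "n_neighbors": self.n_neighbors,
                "subsample_size": anchors.subsample_size,
                "k_method": self.k_method,
                "metric": self.metric,
                "resolution": self.resolution,
                "alpha": self.alpha,
                "fixed_K": self.n_clusters,
            },
            cell_ids=cell_ids,
        )
        return self


class SecuerConsensusClustering(ClusterMixin, BaseEstimator):
    """Consensus clustering over several base runs.

    ``n_runs`` base clusterings are produced with varied anchor seeds,
    alternating Euclidean/cosine metrics and cycling cluster-number
    estimator settings, then aggregated through the unweighted
    cell-cluster incidence graph, partitioned with the same transfer-cut
    machinery as a single run (see :mod:`secuer.consensus`).

    Parameters
    ----------
    n_runs : int, default 5
        Number of base runs M.
    n_clusters : int or None
        Consensus K; ``None`` uses the median of the base runs' cluster
        counts (rounded half up).
    n_jobs : int, default 1
        Base runs are independent and may execute concurrently; results
        are identical to sequential execution.
    Other parameters mirror :class:`SecuerClustering`.

    Attributes
    ----------
    labels_, n_clusters_ : consensus partition.
    ensemble_ : ConsensusEnsemble with the base labelings and incidence.
    """

    def __init__(
        self,
        n_runs: int = 5,
        n_clusters: int | None = None,
        n_anchors: int = 1000,
        n_neighbors: int = 7,
        subsample_size: int | None = None,
        n_jobs: int = 1,
        random_state=None,
    ):
        self.n_runs = n_runs
        self.n_clusters = n_clusters
        self.n_anchors = n_anchors
        self.n_neighbors = n_neighbors
        self.subsample_size = subsample_size
        self.n_jobs = n_jobs
        self.random_state = random_state

    def fit(self, X, y=None):
        from .consensus import consensus_cluster, run_base_clusterings

        values, cell_ids = _resolve_input(X)
        values = validate_data(self, values, accept_sparse="csr", dtype=np.float64)
        rs = check_random_state(self.random_state)
        seed = int(rs.randint(2**31))
        ens = run_base_clusterings(
            values,
            M=self.n_runs,
            seed=seed,
            jobs=self.n_jobs,
            p=self.n_anchors,
            k=self.n_neighbors,
            subsample_size=self.subsample_size,
        )
        result = consensus_cluster(ens, K=self.n_clusters, seed=seed)
        result.cell_ids = cell_ids
        self.ensemble_ = ens
        self.labels_ = result.labels
        self.n_clusters_ = result.n_clusters
        self.result_ = result
        return self
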