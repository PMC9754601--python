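"""Modified approximate k-nearest-anchor search (MAKNN).

Finding each cell's k nearest anchors exactly would cost O(N p d).  MAKNN
avoids that by routing queries through a two-level index built on the
anchors alone:

1. the p anchors are grouped into o = round(sqrt(p)) anchor-clusters by
   k-means;
2. every anchor's exact k' = 10 k nearest anchors are tabulated (a p x k'
   table, cheap because p << N);
3. each cell is assigned to its nearest anchor-cluster center, the nearest
   anchor p(i) within that cluster is found exactly, and the cell's k
   nearest anchors are taken from the candidate set {p(i)} union the k'
   neighbors of p(i).

Per cell this touches o cluster centers, one anchor-cluster and k'+1
candidates instead of all p anchors, giving the O(N sqrt(p) d) graph
construction cost.  The o = sqrt(p) choice balances the routing and
within-cluster search terms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.preprocessing import normalize as l2_normalize

from .anchors import AnchorSet, matrix_values

__all__ = [
    "AnchorIndex",
    "NeighborAssignment",
    "build_anchor_index",
    "query_k_nearest_anchors",
    "pairwise_distances",
]

K_PRIME_FACTOR = 10
VALID_METRICS = ("euclidean", "cosine")


def pairwise_distances(A, B, metric: str = "euclidean") -> np.ndarray:
    """Dense distance block between two small point sets.

    Cosine distance is 1 - cosine similarity; zero-norm vectors are at
    distance 1 from everything (including themselves) by convention.
    """
    if metric == "euclidean":
        return euclidean_distances(A, B)
    if metric == "cosine":
        An = l2_normalize(A, norm="l2", axis=1)
        Bn = l2_normalize(B, norm="l2", axis=1)
        sim = An @ Bn.T
        if sp.issparse(sim):
            sim = np.asarray(sim.todense())
        return np.clip(1.0 - sim, 0.0, 2.0)
    raise ValueError(f"unknown metric {metric!r}")


def _stable_argsort_rows(D: np.ndarray) -> np.ndarray:
    # Stable sort on distance; equal distances keep ascending column order,
    # so ties break toward the lower anchor index.
    return np.argsort(D, axis=1, kind="stable")


@dataclass
class AnchorIndex:
    """Routing structures for approximate nearest-anchor queries."""

    anchor_cluster_of: np.ndarray  # p-vector in [0, o)
    cluster_centers: np.ndarray  # o x d
    anchor_knn: np.ndarray  # p x k' (ascending distance)
    o: int
    k_prime: int
    metric: str

    def __post_init__(self) -> None:
        p = self.anchor_cluster_of.shape[0]
        if not 1 <= self.k_prime <= p - 1:
            raise ValueError("k' must lie in [1, p-1]")
        if self.anchor_knn.shape != (p, self.k_prime):
            raise ValueError("anchor kNN table has the wrong shape")


@dataclass
class NeighborAssignment:
    """Each cell's (approximate) k nearest anchors, ascending by distance."""

    anchor_idx: np.ndarray  # N x k
    dist: np.ndarray  # N x k, sorted ascending per row
    nearest_anchor: np.ndarray  # N-vector: the seed anchor p(i)
    k: int
    metric: str
    n_dist_evals: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.anchor_idx.shape != self.dist.shape:
            raise ValueError("index and distance tables must match in shape")
        if np.any(self.dist < 0) or not np.all(np.isfinite(self.dist)):
            raise ValueError("distances must be finite and nonnegative")
        if np.any(np.diff(self.dist, axis=1) < 0):
            raise ValueError("distances must be sorted ascending per row")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_anchor_index(
    anchors: AnchorSet,
    k: int,
    metric: str = "euclidean",
    seed: int = 0,
    k_prime: int | None = None,
) -> AnchorIndex:
    """Cluster the anchors and tabulate each anchor's exact k' neighbors.

    ``o = round(sqrt(p))`` anchor-clusters (round half up, clamped to
    ``[1, p]``); ``k' = min(10 k, p - 1)`` unless overridden.
    """
    if metric not in VALID_METRICS:
        raise ValueError(f"metric must be one of {VALID_METRICS}")
    if k < 1:
        raise ValueError("k must be at least 1")
    coords = anchors.coords
    p = anchors.p
    if k_prime is None:
        k_prime = min(K_PRIME_FACTOR * k, p - 1)
    k_prime = int(min(max(k_prime, 1), p - 1))
    o = min(max(_round_half_up(math.sqrt(p)), 1), p)

    cluster_input = coords
    if metric == "cosine":
        # spherical routing: cluster direction vectors so Euclidean k-means
        # centers approximate cosine neighborhoods
        cluster_input = l2_normalize(coords, norm="l2", axis=1)
    km = KMeans(n_clusters=o, init="k-means++", n_init=1, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = km.fit_predict(cluster_input)
    centers = km.cluster_centers_

    D = pairwise_distances(coords, coords, metric)
    np.fill_diagonal(D, np.inf)  # self excluded from the neighbor table
    order = _stable_argsort_rows(D)
    anchor_knn = order[:, :k_prime]
    return AnchorIndex(labels, centers, anchor_knn, o, k_prime, metric)


def query_k_nearest_anchors(
    X,
    index: AnchorIndex,
    anchors: AnchorSet,
    k: int,
) -> NeighborAssignment:
    """Approximate k nearest anchors for every cell.

    Each cell is routed to its closest anchor-cluster, matched to the
    nearest anchor ``p(i)`` inside it, and searched exactly over the
    candidate set ``{p(i)} | knn(p(i))``.  The full N x p distance matrix
    is never formed.  When the candidate set covers all anchors
    (``k' = p - 1`` or ``p <= k``) the result equals brute force.
    """
    values = matrix_values(X)
    coords = anchors.coords
    p = anchors.p
    n = values.shape[0]
    if values.shape[1] != coords.shape[1]:
        raise ValueError(
            f"cells have {values.shape[1]} features but anchors have "
            f"{coords.shape[1]}"
        )
    if k < 1:
        raise ValueError("k must be at least 1")
    k_eff = min(k, p)
    if k_eff > index.k_prime + 1:
        raise ValueError(
            f"k={k} exceeds the candidate set size k'+1={index.k_prime + 1}"
        )
    metric = index.metric
    n_evals = 0

    if p <= k:
        # Degenerate: fewer anchors than requested neighbors; brute force.
        D = pairwise_distances(values, coords, metric)
        n_evals += D.size
        order = _stable_argsort_rows(D)[:, :k_eff]
        dist = np.take_along_axis(D, order, axis=1)
        return NeighborAssignment(
            order, dist, order[:, 0].copy(), k_eff, metric, n_evals
        )

    # step 1: route every cell to its nearest anchor-cluster center
    Dc = pairwise_distances(values, index.cluster_centers, metric)
    n_evals += Dc.size
    cell_cluster = np.argmin(Dc, axis=1)

    # step 2: exact nearest anchor within the routed cluster
    nearest = np.empty(n, dtype=np.int64)
    for c in range(index.o):
        cells = np.flatnonzero(cell_cluster == c)
        if cells.size == 0:
            continue
        members = np.flatnonzero(index.anchor_cluster_of == c)
        if members.size == 0:
            # empty anchor-cluster: fall back to the globally usable seed 0
            members = np.arange(p)
        Dm = pairwise_distances(values[cells], coords[members], metric)
        n_evals += Dm.size
        # argmin returns the first minimum; members ascend, so ties break
        # toward the lower anchor index
        nearest[cells] = members[np.argmin(Dm, axis=1)]

    # step 3: exact search over {p(i)} union knn(p(i))
    anchor_idx = np.empty((n, k_eff), dtype=np.int64)
    dist = np.empty((n, k_eff), dtype=np.float64)
    for j in np.unique(nearest):
        cells = np.flatnonzero(nearest == j)
        cand = np.unique(np.concatenate(([j], index.anchor_knn[j])))
        Dj = pairwise_distances(values[cells], coords[cand], metric)
        n_evals += Dj.size
        order = _stable_argsort_rows(Dj)[:, :k_eff]
        anchor_idx[cells] = cand[order]
        dist[cells] = np.take_along_axis(Dj, order, axis=1)

    return NeighborAssignment(anchor_idx, dist, nearest, k_eff, metric, n_evals)
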