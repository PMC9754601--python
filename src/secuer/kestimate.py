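"""Estimating the number of clusters K.

Two estimators are provided:

* **anchor graph** (default): Louvain modularity optimization on the
  anchor-anchor similarity graph W_p = B' D_X^{-1} B (diagonal zeroed).
  The number of communities found at a given resolution is the estimate.
  Working in the p-anchor space keeps the estimate stable even for
  millions of cells, where community detection on the full cell graph
  wildly overestimates K.

* **eigengap**: the number of near-zero eigenvalues of a graph Laplacian
  equals the number of connected components of the graph, so an almost-
  disconnected cluster structure shows up as a group of near-zero
  eigenvalues separated from the rest of the spectrum by a gap.  The
  smallest eigenvalues of the reduced bipartite problem are binned into
  100 equal-width intervals; gaps between consecutive non-empty bins are
  thresholded at the alpha-th greatest gap, and the eigenvalues falling
  before the first qualifying gap are counted.
"""

from __future__ import annotations

import random as _random
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .affinity import BipartiteAffinity
from .spectral import reduced_eigenvalues, reduced_problem

__all__ = [
    "EigengapConfig",
    "estimate_k_anchor_graph",
    "estimate_k_eigengap",
]

#: How many of the smallest reduced eigenvalues feed the eigengap estimator.
K_MAX_EIGENVALUES = 50


@dataclass
class EigengapConfig:
    """Parameters and (after a run) the intermediate state of the binning."""

    n_bins: int = 100
    alpha: int = 4
    #: which qualifying gap terminates the near-zero group: "first" counts
    #: the eigenvalues before the earliest significant gap (the near-zero
    #: group itself), "last" counts everything before the final one.
    select: str = "first"
    bins: list[tuple[float, float]] = field(default_factory=list)
    counts: np.ndarray | None = None
    gaps: np.ndarray | None = None
    u_star: int | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        if self.alpha < 1:
            raise ValueError("alpha must be at least 1")
        if self.select not in ("first", "last"):
            raise ValueError("select must be 'first' or 'last'")


def estimate_k_eigengap(
    lambdas,
    cfg: EigengapConfig | None = None,
) -> int:
    """Count the near-zero eigenvalues below the first significant gap.

    Steps: sort the eigenvalues ascending; rescale to [0, 1] (the binning
    only depends on relative positions, so the estimate is invariant to
    scaling all eigenvalues by c > 0); divide into ``n_bins`` equal-width
    bins; compute the gap between each pair of consecutive *non-empty*
    bins as (left edge of the next) - (right edge of the current);
    threshold at the alpha-th greatest gap (the greatest, if fewer than
    alpha gaps exist); the estimate is the number of eigenvalues at or
    before the first bin whose following gap meets the threshold.
    Degenerate spectra (all eigenvalues equal, or no gap) give 1.
    """
    if cfg is None:
        cfg = EigengapConfig()
    lam = np.sort(np.asarray(lambdas, dtype=np.float64))
    if lam.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    lo, hi = lam[0], lam[-1]
    if hi == lo:
        return 1
    x = (lam - lo) / (hi - lo)
    nb = cfg.n_bins
    edges = np.linspace(0.0, 1.0, nb + 1)
    idx = np.minimum((x * nb).astype(int), nb - 1)
    counts = np.bincount(idx, minlength=nb)
    nonempty = np.flatnonzero(counts)
    cfg.bins = [(edges[u], edges[u + 1]) for u in range(nb)]
    cfg.counts = counts
    if nonempty.size < 2:
        return 1
    # gap after non-empty bin j = L(next non-empty) - R(j)
    gaps = edges[nonempty[1:]] - edges[nonempty[:-1] + 1]
    cfg.gaps = gaps
    order = np.sort(gaps)[::-1]
    delta_alpha = order[min(cfg.alpha, gaps.size) - 1]
    qualifying = np.flatnonzero(gaps >= delta_alpha)
    if qualifying.size == 0 or delta_alpha <= 0:
        return 1
    j = qualifying[0] if cfg.select == "first" else qualifying[-1]
    cfg.u_star = int(nonempty[j])
    return int(counts[: cfg.u_star + 1].sum())


def estimate_k_eigengap_from_affinity(
    aff: BipartiteAffinity,
    cfg: EigengapConfig | None = None,
    k_max: int = K_MAX_EIGENVALUES,
) -> int:
    """Eigengap estimate straight from the bipartite affinity matrix."""
    lam = reduced_eigenvalues(aff, m=k_max)
    return estimate_k_eigengap(lam, cfg)


def estimate_k_anchor_graph(
    aff: BipartiteAffinity,
    resolution: float = 1.0,
    seed: int = 0,
) -> int:
    """Number of Louvain communities of the anchor similarity graph W_p.

    Isolated anchors count as their own communities; a graph with no edges
    at all returns the number of isolated components with a warning.
    """
    import igraph as ig

    graph = reduced_problem(aff)
    W = sp.coo_matrix(sp.triu(graph.W_p, k=1))
    p = graph.W_p.shape[0]
    if W.nnz == 0:
        warnings.warn(
            "anchor graph has no edges; returning isolated component count",
            stacklevel=2,
        )
        return p
    g = ig.Graph(
        n=p,
        edges=list(zip(W.row.tolist(), W.col.tolist())),
        edge_attrs={"weight": W.data.tolist()},
    )
    ig.set_random_number_generator(_random.Random(seed))
    try:
        parts = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        ig.set_random_number_generator(_random)
    return len(parts)
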