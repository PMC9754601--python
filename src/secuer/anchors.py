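"""Anchor selection.

Anchors are landmark points standing in for many cells: the centroids of a
k-means clustering run on a uniform random subsample of the data.  With
``p`` anchors and a subsample of ``p' = 10 p`` cells (capped at N), anchor
selection costs far less than any pairwise cell-cell computation while the
centroids still trace the geometry of the expression landscape.  Datasets
smaller than the subsample size are used in full.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .io import ExpressionMatrix

__all__ = ["AnchorSet", "select_anchors"]

DEFAULT_P = 1000
SUBSAMPLE_FACTOR = 10


def matrix_values(X) -> np.ndarray | sp.spmatrix:
    """Accept an ExpressionMatrix, ndarray or sparse matrix; return values."""
    if isinstance(X, ExpressionMatrix):
        return X.values
    if sp.issparse(X):
        return sp.csr_matrix(X)
    return np.asarray(X, dtype=np.float64)


@dataclass
class AnchorSet:
    """The ``p`` anchor coordinates plus the selection parameters."""

    coords: np.ndarray  # p x d
    p: int
    subsample_size: int
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[0] != self.p:
            raise ValueError("anchor coordinates must be a p x d matrix")
        if self.p < 2:
            raise ValueError("need at least 2 anchors")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("anchor coordinates must be finite")


def select_anchors(
    X,
    p: int = DEFAULT_P,
    subsample_size: int | None = None,
    seed: int = 0,
) -> AnchorSet:
    """Pick ``p`` anchors as k-means centroids of a random cell subsample.

    If the dataset holds fewer cells than ``subsample_size`` (default
    ``10 * p``), k-means runs on all cells directly.  Deterministic given
    ``seed``: the same seed yields bitwise-identical anchors.

    Raises
    ------
    ValueError
        If ``p`` is not in ``[2, N)`` or exceeds the effective subsample.
    """
    values = matrix_values(X)
    n = values.shape[0]
    if p < 2:
        raise ValueError("p must be at least 2")
    if p >= n:
        raise ValueError(f"p={p} must be smaller than the number of cells ({n})")
    if subsample_size is None:
        subsample_size = SUBSAMPLE_FACTOR * p
    subsample_size = min(int(subsample_size), n)
    if p > subsample_size:
        raise ValueError(
            f"p={p} exceeds the effective subsample size {subsample_size}"
        )
    rng = np.random.default_rng(seed)
    if n > subsample_size:
        idx = rng.choice(n, size=subsample_size, replace=False)
        sub = values[np.sort(idx)]
    else:
        sub = values
    km = KMeans(
        n_clusters=p,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-4,
        random_state=int(rng.integers(2**31)),
    )
    with warnings.catch_warnings():
        # sklearn warns when duplicate points force fewer distinct centers;
        # its empty-cluster repair still returns exactly p centroids.
        warnings.simplefilter("ignore")
        km.fit(sub)
    return AnchorSet(km.cluster_centers_, p, subsample_size, seed)


def clamp_anchor_count(p: int, n: int) -> int:
    """Clamp a requested anchor count to at most ``n // 2`` for tiny inputs.

    Each anchor should summarize at least two cells; pipelines call this so
    default parameters work on toy data, while :func:`select_anchors` itself
    stays strict.
    """
    if p >= n:
        clamped = max(2, n // 2)
        warnings.warn(
            f"anchor count {p} >= n_cells {n}; clamped to {clamped}",
            stacklevel=2,
        )
        return clamped
    return p
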