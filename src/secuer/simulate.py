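"""Deterministic synthetic datasets with known labels.

Two generators exercise every pipeline stage without any download: a
Gaussian mixture with centroids placed on a scaled simplex (so the
requested centroid separation is exact, not sampled) for geometry-level
tests, and overdispersed negative-binomial counts with group-specific
differentially expressed genes emulating the sparsity and mean-variance
structure that the preprocessing pipeline assumes for raw scRNA-seq data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .io import ExpressionMatrix

__all__ = ["SyntheticDataset", "gaussian_mixture", "nb_counts"]


@dataclass
class SyntheticDataset:
    """A labeled synthetic matrix plus the parameters that generated it."""

    matrix: ExpressionMatrix
    labels: np.ndarray
    spec: dict[str, Any] = field(default_factory=dict)
    centroids: np.ndarray | None = None


def _simplex_centroids(G: int, d: int, separation: float) -> np.ndarray:
    """G points in R^d with all pairwise distances exactly ``separation``.

    A regular (G-1)-simplex needs d >= G - 1 dimensions; the unit-scaled
    construction takes the standard basis corners of R^G, centers them,
    projects onto their (G-1)-dimensional span and rescales.
    """
    if G == 1:
        return np.zeros((1, d))
    if d < G - 1:
        raise ValueError(
            f"{G} equidistant centroids need at least {G - 1} dimensions, got {d}"
        )
    corners = np.eye(G) - 1.0 / G  # centered; pairwise distance sqrt(2)
    # orthonormal basis of the span via SVD; G-1 nonzero singular values
    _, s, Vt = np.linalg.svd(corners, full_matrices=False)
    proj = corners @ Vt[: G - 1].T  # G x (G-1)
    proj *= separation / np.sqrt(2.0)
    out = np.zeros((G, d))
    out[:, : G - 1] = proj
    return out


def _group_sizes(n: int, G: int) -> np.ndarray:
    sizes = np.full(G, n // G)
    sizes[: n % G] += 1
    return sizes


def gaussian_mixture(
    n: int,
    d: int,
    G: int,
    separation: float,
    seed: int = 0,
) -> SyntheticDataset:
    """Mixture of G unit-variance isotropic Gaussians, near-equal sizes.

    Centroid pairwise distances all equal ``separation`` exactly; rows are
    shuffled so cluster membership carries no ordering signal.
    """
    if G < 1:
        raise ValueError("G must be at least 1")
    if n < G:
        raise ValueError("need at least one cell per group")
    rng = np.random.default_rng(seed)
    centroids = _simplex_centroids(G, d, separation)
    sizes = _group_sizes(n, G)
    labels = np.repeat(np.arange(G), sizes)
    X = rng.standard_normal((n, d)) + centroids[labels]
    perm = rng.permutation(n)
    X, labels = X[perm], labels[perm]
    matrix = ExpressionMatrix(X, layer_tag="gaussian_mixture")
    return SyntheticDataset(
        matrix,
        labels,
        spec={
            "generator": "gaussian_mixture",
            "n": n,
            "d": d,
            "G": G,
            "separation": separation,
            "seed": seed,
        },
        centroids=centroids,
    )


def nb_counts(
    n: int,
    g_genes: int,
    G: int,
    de_frac: float = 0.1,
    fold: float = 4.0,
    dispersion: float = 0.5,
    seed: int = 0,
) -> SyntheticDataset:
    """Negative-binomial count matrix with group-specific DE genes.

    Baseline gene means are lognormal; each group multiplies the means of
    its own disjoint block of ``de_frac * g_genes`` genes by ``fold``.
    Counts are NB with variance mu + dispersion * mu^2.
    """
    if G < 1 or n < G:
        raise ValueError("need G >= 1 and at least one cell per group")
    if not 0 < de_frac <= 1:
        raise ValueError("de_frac must lie in (0, 1]")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.5, sigma=0.7, size=g_genes)
    n_de = max(1, int(round(de_frac * g_genes)))
    if n_de * G > g_genes:
        raise ValueError(
            f"{G} disjoint DE blocks of {n_de} genes do not fit in {g_genes}"
        )
    de_order = rng.permutation(g_genes)
    means = np.tile(base, (G, 1))
    de_genes = []
    for g in range(G):
        block = de_order[g * n_de : (g + 1) * n_de]
        means[g, block] *= fold
        de_genes.append(np.sort(block))
    sizes = _group_sizes(n, G)
    labels = np.repeat(np.arange(G), sizes)
    mu = means[labels]
    r = 1.0 / dispersion  # NB shape: var = mu + dispersion * mu^2
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.float64)
    perm = rng.permutation(n)
    counts, labels = counts[perm], labels[perm]
    matrix = ExpressionMatrix(counts, layer_tag="nb_counts")
    return SyntheticDataset(
        matrix,
        labels,
        spec={
            "generator": "nb_counts",
            "n": n,
            "g_genes": g_genes,
            "G": G,
            "de_frac": de_frac,
            "fold": fold,
            "dispersion": dispersion,
            "seed": seed,
            "de_genes": [b.tolist() for b in de_genes],
        },
    )
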