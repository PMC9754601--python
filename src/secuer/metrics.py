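"""Clustering agreement metrics: ARI and NMI.

Both are computed from the contingency table of two partitions of the
same N items.  The adjusted Rand index is pair-counting,

    ARI = [sum_st C(N_st,2) - sum_s C(N_s,2) sum_t C(N_t,2)/C(N,2)] /
          [ (sum_s C(N_s,2) + sum_t C(N_t,2))/2
            - sum_s C(N_s,2) sum_t C(N_t,2)/C(N,2) ],

0 in expectation for independent labelings and 1 for identical ones.  NMI
normalizes the mutual information by the arithmetic mean of the two
entropies; the logarithm base cancels.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["ari", "nmi", "contingency_table"]


def _as_labels(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return a, b


def contingency_table(a, b) -> np.ndarray:
    """Dense contingency counts N_st between two label vectors."""
    a, b = _as_labels(a, b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = sp.coo_matrix(
        (np.ones(a.size, dtype=np.int64), (ai, bi)),
        shape=(ai.max() + 1, bi.max() + 1),
    ).toarray()
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    # exact integer pair counts; stays in Python ints via object only when
    # needed -- int64 covers n < ~4e9 pairs, far beyond single-cell scale
    x = x.astype(np.int64)
    return x * (x - 1) // 2


def ari(a, b) -> float:
    """Adjusted Rand index in [-1, 1]; 1 iff the partitions are identical.

    Symmetric and invariant to label renaming.  The degenerate case where
    the index and its expectation coincide (e.g. both partitions trivial)
    returns 1 by convention.
    """
    table = contingency_table(a, b)
    n = table.sum()
    sum_cells = _comb2(table).sum()
    sum_rows = _comb2(table.sum(axis=1)).sum()
    sum_cols = _comb2(table.sum(axis=0)).sum()
    total = _comb2(np.array([n]))[0]
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def nmi(a, b) -> float:
    """Normalized mutual information in [0, 1], arithmetic-mean normalization.

    If either partition has a single cluster its entropy is 0 and the 0/0
    convention returns 0.
    """
    table = contingency_table(a, b).astype(np.float64)
    n = table.sum()
    P = table / n
    Ps = P.sum(axis=1)
    Pt = P.sum(axis=0)
    nz = P > 0
    outer = np.outer(Ps, Pt)
    mi = float(np.sum(P[nz] * np.log(P[nz] / outer[nz])))
    h_s = float(-np.sum(Ps[Ps > 0] * np.log(Ps[Ps > 0])))
    h_t = float(-np.sum(Pt[Pt > 0] * np.log(Pt[Pt > 0])))
    denom = 0.5 * (h_s + h_t)
    if denom == 0:
        return 0.0
    return mi / denom
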