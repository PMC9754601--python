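"""Consensus clustering over multiple base runs.

M base clusterings are aggregated through an unweighted bipartite graph
between the N cells and the union of all K_C = sum K_m base clusters: the
N x K_C incidence matrix E has E[i, h] = 1 exactly when cell i belongs to
cluster h of some run, so every row sums to M.  Partitioning this graph
with the same transfer-cut reduction used for the cell-anchor graph -- the
incidence matrix simply takes the place of the affinity matrix B -- yields
a consensus labeling that rewards groups of cells the base runs keep
placing together.

Base runs are varied three ways: per-run anchor-selection seeds,
alternating Euclidean/cosine distance metrics, and cycling cluster-number
estimator settings (anchor-graph Louvain at resolutions 0.5 / 1.0 / 1.5,
then the eigengap estimator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
from joblib import Parallel, delayed

from .affinity import BipartiteAffinity
from .spectral import ClusteringResult, row_normalize, tcut_embedding

__all__ = [
    "ConsensusEnsemble",
    "run_base_clusterings",
    "consensus_cluster",
    "secuer_consensus",
]

#: (k_method, resolution) settings cycled across base runs.
K_SETTING_CYCLE = (
    ("anchor_graph", 0.5),
    ("anchor_graph", 1.0),
    ("anchor_graph", 1.5),
    ("eigengap", None),
)
METRIC_CYCLE = ("euclidean", "cosine")


@dataclass
class ConsensusEnsemble:
    """M base labelings and the cell-cluster incidence matrix built from them."""

    labelings: list[np.ndarray]
    K_m: list[int]
    incidence: sp.csr_matrix  # N x K_C binary
    run_params: list[dict[str, Any]] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.labelings)

    @property
    def K_C(self) -> int:
        return self.incidence.shape[1]


def build_incidence(labelings: list[np.ndarray]) -> sp.csr_matrix:
    """Stack one-hot encodings of the base labelings; drop empty clusters."""
    if not labelings:
        raise ValueError("need at least one base labeling")
    n = labelings[0].size
    blocks = []
    for lab in labelings:
        lab = np.asarray(lab, dtype=int)
        if lab.size != n:
            raise ValueError("base labelings must have equal length")
        _, dense = np.unique(lab, return_inverse=True)  # drops empty clusters
        k = dense.max() + 1
        blocks.append(
            sp.csr_matrix(
                (np.ones(n), (np.arange(n), dense)), shape=(n, k)
            )
        )
    return sp.csr_matrix(sp.hstack(blocks))


def run_base_clusterings(
    X,
    M: int = 5,
    seed: int = 0,
    jobs: int = 1,
    p: int = 1000,
    k: int = 7,
    subsample_size: int | None = None,
) -> ConsensusEnsemble:
    """Execute M varied base runs and assemble the incidence matrix.

    Each run m gets its own pre-assigned seed, the metric alternates
    Euclidean/cosine, and the K-estimator settings cycle; runs are
    independent, so concurrent execution (``jobs > 1``) returns exactly
    the sequential result.  A failing run is skipped with a warning; all
    runs failing is an error.
    """
    from .cluster import SecuerClustering, _sub_seeds

    if M < 1:
        raise ValueError("M must be at least 1")
    seeds = _sub_seeds(seed, M)

    def one_run(m: int):
        k_method, resolution = K_SETTING_CYCLE[m % len(K_SETTING_CYCLE)]
        est = SecuerClustering(
            n_anchors=p,
            n_neighbors=k,
            subsample_size=subsample_size,
            k_method=k_method,
            metric=METRIC_CYCLE[m % len(METRIC_CYCLE)],
            resolution=resolution if resolution is not None else 1.0,
            random_state=seeds[m],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X)
        return est.labels_, est.n_clusters_, est.result_.params | {
            "seed": seeds[m]
        }

    runner = Parallel(n_jobs=jobs) if jobs != 1 else None
    outputs = []
    if runner is not None:
        tasks = [delayed(one_run)(m) for m in range(M)]
        try:
            outputs = runner(tasks)
        except Exception:
            runner = None  # fall through to sequential with per-run handling
    if runner is None and not outputs:
        for m in range(M):
            try:
                outputs.append(one_run(m))
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"base run {m} failed: {exc}", stacklevel=2)
    if not outputs:
        raise RuntimeError("all base clustering runs failed")

    labelings = [out[0] for out in outputs]
    K_m = [int(out[1]) for out in outputs]
    run_params = [out[2] for out in outputs]
    incidence = build_incidence(labelings)
    return ConsensusEnsemble(labelings, K_m, incidence, run_params)


def _median_half_up(values) -> int:
    med = float(np.median(np.asarray(values, dtype=float)))
    return int(np.floor(med + 0.5))


def consensus_cluster(
    ens: ConsensusEnsemble,
    K: int | None = None,
    seed: int = 0,
) -> ClusteringResult:
    """Partition the cell-cluster incidence graph into K consensus clusters.

    The incidence matrix is treated exactly as the cell-anchor affinity:
    transfer-cut reduction to a K_C x K_C problem, lift to the cells,
    row-normalize, k-means.  ``K`` defaults to the median base-run cluster
    count (rounded half up).
    """
    from sklearn.cluster import KMeans

    from .cluster import _sub_seeds

    if ens.M < 1:
        raise ValueError("ensemble is empty")
    if K is None:
        K = _median_half_up(ens.K_m)
    K = int(K)
    if K < 1 or K > ens.K_C:
        raise ValueError(f"K={K} must lie in [1, K_C={ens.K_C}]")
    aff = BipartiteAffinity(ens.incidence, sigma=None, k=ens.M, metric="incidence")
    emb = tcut_embedding(aff, K)
    Tn = row_normalize(emb.T)
    s_kmeans = _sub_seeds(seed, 1)[0]
    labels = KMeans(
        n_clusters=K, init="k-means++", n_init=10, random_state=s_kmeans
    ).fit_predict(Tn)
    return ClusteringResult(
        labels,
        K,
        seed=seed,
        params={"M": ens.M, "K_m": ens.K_m, "K_C": ens.K_C},
    )


def secuer_consensus(
    X,
    M: int = 5,
    K: int | None = None,
    seed: int = 0,
    jobs: int = 1,
    p: int = 1000,
    k: int = 7,
    subsample_size: int | None = None,
) -> ClusteringResult:
    """Functional wrapper over :class:`secuer.cluster.SecuerConsensusClustering`."""
    from .cluster import SecuerConsensusClustering

    est = SecuerConsensusClustering(
        n_runs=M,
        n_clusters=K,
        n_anchors=p,
        n_neighbors=k,
        subsample_size=subsample_size,
        n_jobs=jobs,
        random_state=seed,
    )
    est.fit(X)
    return est.result_
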