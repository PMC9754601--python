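# secuer

Anchor-based bipartite-graph spectral clustering for single-cell RNA-seq,
with a consensus extension.

## The problem

Unsupervised clustering assigns the N cells of an expression matrix
`X ∈ R^{N×d}` to putative cell types. Classical spectral clustering does
this well but needs an N×N similarity matrix (`O(N²d)` to build) and its
eigenvectors (`O(N³)`), which is hopeless for the million-cell datasets
modern atlases produce. Graph-based community detection (Louvain/Leiden)
scales better but drastically overestimates the number of clusters on
very large data.

This package implements an anchor (landmark) formulation that keeps the
spectral machinery but replaces every cell-cell computation with
cell-anchor ones:

1. **Anchors.** Select `p` anchors (default 1000) as k-means centroids of
   a uniform subsample of `p' = 10p` cells (datasets below the subsample
   size are used whole).
2. **Approximate nearest anchors.** For each cell, find its `k` (default
   7) nearest anchors approximately: the anchors are pre-clustered into
   `o = √p` groups and each anchor's exact `k' = 10k` nearest anchors are
   tabulated; a query routes through the nearest group, matches the
   nearest anchor `p⁽ⁱ⁾` inside it, and searches only
   `{p⁽ⁱ⁾} ∪ knn(p⁽ⁱ⁾)`. Graph construction costs `O(N√p·d)` instead of
   `O(N²d)`.
3. **Locally scaled affinities.** The bipartite weight is
   `b_ij = exp(−‖x_i − r_j‖² / 2σ_i²)` for the k nearest anchors and 0
   otherwise, with `σ_i` the mean distance from cell i to those anchors —
   a per-cell bandwidth that adapts to local density.
4. **Transfer cut.** With `W = [[0, B], [Bᵀ, 0]]`, the generalized
   eigenproblem `Lv = γDv` on all N+p nodes reduces exactly to the p×p
   problem `L_p z = λ D_p z`, `W_p = Bᵀ D_X⁻¹ B`, whose eigenpairs map
   back through `γ(2−γ) = λ` and `ξ = P z / (1−γ)`, `P = D_X⁻¹ B`. The
   row-normalized lifted vectors are clustered by k-means.
5. **How many clusters?** Either Louvain community detection on the
   anchor graph `W_p` (default), or counting the near-zero eigenvalues of
   the reduced Laplacian via an eigenvalue-gap binning rule.

The consensus variant runs the pipeline M times (default 5) with varied
seeds, metrics (Euclidean/cosine) and cluster-number settings, builds the
unweighted N×K_C cell-cluster incidence graph from the base labelings,
and partitions it with the same transfer-cut reduction.

## Worked example

```python
from secuer import SecuerClustering, ari, nmi, gaussian_mixture

# 3000 cells, 10 dims, 3 groups at 10x the within-group spread
ds = gaussian_mixture(n=3000, d=10, G=3, separation=10.0, seed=0)

est = SecuerClustering(random_state=0).fit(ds.matrix)
print(f"estimated K      : {est.n_clusters_}")
print(f"ARI vs truth     : {ari(est.labels_, ds.labels):.3f}")
print(f"NMI vs truth     : {nmi(est.labels_, ds.labels):.3f}")
print(f"anchors, k       : {est.anchors_.p}, {est.neighbor_assignment_.k}")
print(f"affinity nnz     : {est.affinity_.B.nnz}")
```

prints

```
estimated K      : 3
ARI vs truth     : 1.000
NMI vs truth     : 1.000
anchors, k       : 1000, 7
affinity nnz     : 21000
```

The estimator found K = 3 on its own (Louvain on the anchor graph),
recovered the generating partition exactly (ARI = NMI = 1), and the only
cell-level structure it built is the sparse affinity matrix with
N·k = 21000 entries — not the 9-million-entry cell-cell matrix vanilla
spectral clustering would need.

The estimators follow the scikit-learn contract (`fit`, `fit_predict`,
`get_params`/`set_params`, `labels_`, `n_clusters_`), so they drop into
sklearn pipelines; `secuer.secuer()` and `secuer.secuer_consensus()` are
one-call functional wrappers.

From the shell:

```sh
secuer simulate --preset blobs --n 3000 --groups 3 --out blobs.csv
secuer run --input blobs.csv --seed 0 --output labels.csv
secuer score --pred labels.csv --ref blobs.csv.labels.csv
secuer consensus --input blobs.csv -M 5 --output consensus.csv
```

`secuer run` also reads 10x-style Matrix Market triplets (with
`barcodes.tsv`/`features.tsv` alongside) and H5AD; `--preprocess` applies
the standard filter → library-size-normalize → log1p → HVG → PCA pipeline
first (see `secuer.preprocess`).

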