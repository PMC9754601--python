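"""Optional preprocessing: raw counts to the PC-score matrix.

The pipeline applies, in order: gene/cell filtering, per-cell library-size
normalization, log(1+x), highly-variable-gene selection, optional scaling,
and PCA.  Every stage can be skipped individually.  Two filtering presets
are provided: the fraction-based rule (drop genes expressed in fewer than
10% or more than 90% of cells), appropriate for small well-annotated
datasets, and count thresholds (min genes per cell / min cells per gene)
for larger data.  Standard steps are delegated to scanpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix

__all__ = ["PreprocessConfig", "preprocess"]


@dataclass
class PreprocessConfig:
    """Stage parameters; ``None`` (or False) disables the stage.

    Parameters
    ----------
    gene_min_frac, gene_max_frac
        Keep genes expressed in a fraction of cells within
        ``[gene_min_frac, gene_max_frac]``; ``None`` disables the
        fraction filter (the large-data preset).
    min_genes_per_cell, min_cells_per_gene
        Count-threshold filters, the large-data alternative.
    mito_max_frac
        Optional cap on the mitochondrial UMI fraction per cell
        (``mito_prefix`` names the genes); disabled by default.
    target_sum
        Per-cell total after library-size normalization (default 1e4,
        the common single-cell convention).
    n_hvg
        Highly variable genes kept, ranked by normalized dispersion.
    n_pcs
        Principal components retained (default 50).
    do_log, do_scale
        Toggle the log(1+x) transform and unit-variance scaling.
    """

    gene_min_frac: float | None = 0.10
    gene_max_frac: float | None = 0.90
    min_genes_per_cell: int | None = None
    min_cells_per_gene: int | None = None
    mito_max_frac: float | None = None
    mito_prefix: str = "MT-"
    target_sum: float | None = 1e4
    n_hvg: int | None = 2000
    n_pcs: int | None = 50
    do_log: bool = True
    do_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_min_frac is not None and self.gene_max_frac is not None:
            if not 0 <= self.gene_min_frac < self.gene_max_frac <= 1:
                raise ValueError("need 0 <= gene_min_frac < gene_max_frac <= 1")
        if self.n_pcs is not None and self.n_pcs < 1:
            raise ValueError("n_pcs must be at least 1")

    @classmethod
    def gold_standard(cls, **kw) -> "PreprocessConfig":
        """Fraction-based gene filtering, for small annotated datasets."""
        return cls(**kw)

    @classmethod
    def large_data(
        cls,
        min_genes_per_cell: int = 200,
        min_cells_per_gene: int = 3,
        **kw,
    ) -> "PreprocessConfig":
        """Count-threshold filtering, for atlas-scale datasets."""
        return cls(
            gene_min_frac=None,
            gene_max_frac=None,
            min_genes_per_cell=min_genes_per_cell,
            min_cells_per_gene=min_cells_per_gene,
            **kw,
        )

    @classmethod
    def identity(cls) -> "PreprocessConfig":
        """All stages disabled: output equals input."""
        return cls(
            gene_min_frac=None,
            gene_max_frac=None,
            target_sum=None,
            n_hvg=None,
            n_pcs=None,
            do_log=False,
            do_scale=False,
        )


def _filter(adata, cfg: PreprocessConfig):
    import scanpy as sc

    if cfg.min_genes_per_cell is not None:
        sc.pp.filter_cells(adata, min_genes=cfg.min_genes_per_cell)
    if cfg.min_cells_per_gene is not None:
        sc.pp.filter_genes(adata, min_cells=cfg.min_cells_per_gene)
    if cfg.gene_min_frac is not None and cfg.gene_max_frac is not None:
        X = adata.X
        expressed = (X > 0).sum(axis=0)
        frac = np.asarray(expressed).ravel() / max(adata.n_obs, 1)
        keep = (frac >= cfg.gene_min_frac) & (frac <= cfg.gene_max_frac)
        adata = adata[:, keep].copy()
    if cfg.mito_max_frac is not None:
        mito = np.array(
            [name.upper().startswith(cfg.mito_prefix.upper())
             for name in adata.var_names]
        )
        totals = np.asarray(adata.X.sum(axis=1)).ravel()
        mito_sum = np.asarray(adata[:, mito].X.sum(axis=1)).ravel() if mito.any() \
            else np.zeros(adata.n_obs)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_sum / totals, 0.0)
        adata = adata[frac <= cfg.mito_max_frac].copy()
    return adata


def preprocess(raw: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Run the preprocessing pipeline on a raw count matrix.

    Returns the N x n_pcs PC-score matrix tagged ``"pca"`` (or, with PCA
    disabled, the transformed expression matrix).  Raises if filtering
    empties the matrix or ``n_pcs`` exceeds the remaining feature count.
    """
    import anndata
    import scanpy as sc

    if cfg is None:
        cfg = PreprocessConfig()
    X = raw.values
    if sp.issparse(X):
        if np.any(X.data < 0):
            raise ValueError("raw counts must be nonnegative")
    elif np.any(X < 0):
        raise ValueError("raw counts must be nonnegative")
    adata = anndata.AnnData(
        X=sp.csr_matrix(X) if sp.issparse(X) else X.copy(),
        obs={"obs_names": list(raw.cell_ids)},
        var={"var_names": list(raw.feature_ids)},
    )
    adata.obs_names = list(raw.cell_ids)
    adata.var_names = list(raw.feature_ids)

    adata = _filter(adata, cfg)
    if adata.n_obs == 0:
        raise ValueError("filtering removed every cell")
    if adata.n_vars == 0:
        raise ValueError("filtering removed every gene")

    if cfg.target_sum is not None:
        sc.pp.normalize_total(adata, target_sum=cfg.target_sum)
    if cfg.do_log:
        sc.pp.log1p(adata)
    if cfg.n_hvg is not None and cfg.n_hvg < adata.n_vars:
        sc.pp.highly_variable_genes(
            adata, n_top_genes=cfg.n_hvg, flavor="seurat"
        )
        adata = adata[:, adata.var["highly_variable"]].copy()
    if cfg.do_scale:
        sc.pp.scale(adata)

    if cfg.n_pcs is None:
        values = adata.X
        return ExpressionMatrix(
            np.asarray(values.todense()) if sp.issparse(values) else np.asarray(values),
            adata.obs_names.tolist(),
            adata.var_names.tolist(),
            layer_tag="preprocessed",
        )
    max_pcs = min(adata.n_obs - 1, adata.n_vars - 1)
    if cfg.n_pcs > max_pcs:
        raise ValueError(
            f"n_pcs={cfg.n_pcs} exceeds the available rank {max_pcs} "
            "after filtering"
        )
    sc.pp.pca(
        adata,
        n_comps=cfg.n_pcs,
        svd_solver="arpack",  # deterministic for <= 50 components
        zero_center=True,
        random_state=cfg.seed,
    )
    scores = np.asarray(adata.obsm["X_pca"], dtype=np.float64)
    return ExpressionMatrix(
        scores,
        adata.obs_names.tolist(),
        [f"PC{i + 1}" for i in range(scores.shape[1])],
        layer_tag="pca",
    )
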