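"""Reading cell-by-feature matrices and writing clustering outputs.

Supported input formats are Matrix Market triplet files with companion
barcode/feature lists (the 10x Genomics on-disk dialect), delimited text
(CSV/TSV with a header row of feature names and a first column of cell
identifiers), and H5AD single-cell containers.  All readers return an
:class:`ExpressionMatrix`, the cells-by-features container that every
downstream stage consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "write_labels",
    "read_labels",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} identifiers are not unique")
    return ids


@dataclass
class ExpressionMatrix:
    """A cells x features numeric matrix with identifiers attached.

    Parameters
    ----------
    values
        N x d matrix of raw counts or continuous scores.  May be a dense
        ndarray or any scipy sparse matrix; sparse inputs are kept sparse
        (CSR) internally.
    cell_ids, feature_ids
        Row and column identifiers; must be unique and match the matrix
        dimensions.
    layer_tag
        Free-text provenance tag, e.g. ``"raw"`` or ``"pca"``.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
            finite = np.all(np.isfinite(self.values.data))
        else:
            self.values = np.asarray(self.values, dtype=np.float64)
            if self.values.ndim != 2:
                raise ValueError("expression matrix must be two-dimensional")
            finite = bool(np.all(np.isfinite(self.values)))
        n, d = self.values.shape
        if n < 2 or d < 1:
            raise ValueError(f"matrix must be at least 2 x 1, got {n} x {d}")
        if not finite:
            raise ValueError("expression matrix contains non-finite values")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"feature_{j}" for j in range(d)]
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        if len(self.cell_ids) != n:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(self.feature_ids) != d:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {d} matrix columns"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return self.values


def _find_companion(mtx_path: Path, stems: Sequence[str]) -> Path | None:
    for stem in stems:
        for suffix in (".tsv", ".txt", ".csv"):
            cand = mtx_path.parent / f"{stem}{suffix}"
            if cand.exists():
                return cand
    return None


def _read_id_file(path: Path) -> list[str]:
    # 10x companion files are one record per line; features.tsv may carry
    # extra columns (gene symbol, feature type) -- the first column is the id.
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def _read_mtx(
    path: Path,
    cells_as_rows: bool,
    barcodes: Path | None,
    features: Path | None,
) -> ExpressionMatrix:
    mat = sp.csr_matrix(scipy.io.mmread(path))
    if barcodes is None:
        bpath = _find_companion(path, ["barcodes"])
    else:
        bpath = Path(barcodes)
    if features is None:
        fpath = _find_companion(path, ["features", "genes"])
    else:
        fpath = Path(features)
    if not cells_as_rows:
        # 10x convention: stored genes x cells; transpose to cells x genes.
        mat = sp.csr_matrix(mat.T)
    n, d = mat.shape
    cell_ids = _read_id_file(bpath) if bpath else []
    feature_ids = _read_id_file(fpath) if fpath else []
    if cell_ids and len(cell_ids) != n:
        raise ValueError(
            f"barcode file lists {len(cell_ids)} cells but matrix has {n}"
        )
    if feature_ids and len(feature_ids) != d:
        raise ValueError(
            f"feature file lists {len(feature_ids)} features but matrix has {d}"
        )
    return ExpressionMatrix(mat, cell_ids, feature_ids, layer_tag="raw")


def _read_delimited(path: Path) -> ExpressionMatrix:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
    return ExpressionMatrix(
        values,
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        layer_tag="raw",
    )


def _read_h5ad(path: Path) -> ExpressionMatrix:
    import anndata  # deferred: pulls in the h5py stack

    adata = anndata.read_h5ad(path)
    X = adata.X
    if sp.issparse(X):
        X = sp.csr_matrix(X)
    else:
        X = np.asarray(X)
    return ExpressionMatrix(
        X,
        adata.obs_names.tolist(),
        adata.var_names.tolist(),
        layer_tag="raw",
    )


def read_matrix(
    path: str | Path,
    format_hint: str = "auto",
    cells_as_rows: bool = False,
    barcodes: str | Path | None = None,
    features: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a cells x features matrix from MTX, CSV/TSV or H5AD.

    Parameters
    ----------
    path
        Input file.  For MTX, companion ``barcodes.tsv`` and
        ``features.tsv``/``genes.tsv`` files are discovered next to the
        matrix unless given explicitly.
    format_hint
        One of ``{"auto", "mtx", "csv", "h5ad"}``; ``auto`` dispatches on
        the file extension.
    cells_as_rows
        For MTX only.  ``False`` (default) assumes the on-disk matrix is
        stored genes x cells (the 10x convention) and transposes it;
        ``True`` takes the stored rows as cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix == ".mtx" or path.name.endswith(".mtx.gz"):
            fmt = "mtx"
        elif suffix in {".csv", ".tsv", ".txt"}:
            fmt = "csv"
        elif suffix in {".h5ad", ".h5"}:
            fmt = "h5ad"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if fmt == "mtx":
        return _read_mtx(path, cells_as_rows, barcodes, features)
    if fmt == "csv":
        return _read_delimited(path)
    if fmt == "h5ad":
        return _read_h5ad(path)
    raise ValueError(f"unknown format {format_hint!r}")


def write_labels(result, path: str | Path) -> None:
    """Write cluster labels as two-column delimited text plus a JSON report.

    The label file has a ``cell_id,cluster`` header followed by one row per
    cell in input order, labels as 0-based integers.  A sidecar
    ``<path>.json`` records the run parameters, seed and cluster count.
    """
    path = Path(path)
    labels = np.asarray(result.labels, dtype=int)
    cell_ids = list(result.cell_ids) if result.cell_ids else [
        f"cell_{i}" for i in range(labels.size)
    ]
    if len(cell_ids) != labels.size:
        raise ValueError("one label per cell id is required")
    df = pd.DataFrame({"cell_id": cell_ids, "cluster": labels})
    df.to_csv(path, index=False)
    report = {
        "n_cells": int(labels.size),
        "n_clusters": int(result.n_clusters),
        "seed": result.seed,
        "params": result.params,
    }
    with open(path.with_name(path.name + ".json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a label file written by :func:`write_labels`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"cell_id": str, "cluster": int})
    if list(df.columns) != ["cell_id", "cluster"]:
        raise ValueError(f"{path} is not a label file")
    return df
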