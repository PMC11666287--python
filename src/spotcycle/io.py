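"""Reading, writing and preprocessing of ST and scRNA-seq matrices.

Supported on-disk layouts
-------------------------
``mtx_dir``
    10x-style triplet ``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv``
    plus a ``coordinates.tsv`` (spot_id, x, y) for spatial data or an
    ``annotations.tsv`` (cell_id, <columns...>) for single-cell data. The
    matrix may be stored genes × spots (10x convention) or spots × genes;
    orientation is resolved against the id files.
``csv``
    Dense table, header row = gene names, index column = spot/cell ids.
    Spatial CSVs carry ``x``/``y`` coordinate columns; single-cell CSVs carry
    the annotation column named by ``annotation_key``.
``h5ad``
    AnnData container; spatial coordinates read from ``obsm["spatial"]``.

Highly-variable-gene selection is a seurat-style normalized-dispersion
ranking (via scanpy) on log1p library-size-normalized counts; gene
harmonization takes the lexicographically sorted intersection so runs are
reproducible independent of input order.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datasets import AnnotationMatrix, SingleCellDataset, SpatialDataset

__all__ = [
    "load_spatial",
    "load_single_cell",
    "select_hvgs",
    "harmonize_genes",
    "build_annotation_matrix",
    "normalize_expression",
    "write_spatial",
    "write_single_cell",
]

_COORD_COLS = ("x", "y")


def _read_mtx_dir(path: Path):
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"no matrix.mtx under {path}")
    mat = scipy.io.mmread(str(mtx))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64)
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).to_numpy()
    # 10x stores genes x barcodes; accept either orientation.
    if mat.shape == (len(features), len(barcodes)):
        mat = mat.T
    elif mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mat.shape} matches neither orientation of "
            f"{len(barcodes)} barcodes x {len(features)} features")
    return mat, barcodes, features


def load_spatial(path, format: str | None = None) -> SpatialDataset:
    """Load a spot × gene expression matrix plus 2-D coordinates.

    ``format`` is one of ``{"mtx_dir", "csv", "h5ad"}``; if omitted it is
    inferred from the path (directory → mtx_dir, suffix otherwise).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx_dir":
        mat, barcodes, features = _read_mtx_dir(path)
        coord_file = path / "coordinates.tsv"
        if not coord_file.exists():
            raise FileNotFoundError("coordinates required: no coordinates.tsv found")
        coords = pd.read_csv(coord_file, sep="\t", index_col=0)
        coords.index = coords.index.astype(str)
        coords = coords.loc[barcodes, ["x", "y"]].to_numpy(dtype=np.float64)
        return SpatialDataset(mat, coords, barcodes, features)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        missing = [c for c in _COORD_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"coordinates required: CSV lacks column(s) {missing}")
        coords = df[list(_COORD_COLS)].to_numpy(dtype=np.float64)
        expr = df.drop(columns=list(_COORD_COLS))
        return SpatialDataset(expr.to_numpy(dtype=np.float64), coords,
                              df.index.astype(str).to_numpy(),
                              expr.columns.astype(str).to_numpy())
    if fmt == "h5ad":
        import anndata as ad
        adata = ad.read_h5ad(path)
        if "spatial" not in adata.obsm:
            raise ValueError('coordinates required: no obsm["spatial"] in h5ad')
        X = adata.X.toarray() if scipy.sparse.issparse(adata.X) else np.asarray(adata.X)
        return SpatialDataset(X, np.asarray(adata.obsm["spatial"])[:, :2],
                              adata.obs_names.to_numpy(),
                              adata.var_names.to_numpy())
    raise ValueError(f"unknown format {fmt!r}")


def load_single_cell(path, format: str | None = None,
                     annotation_key: str = "cell_type") -> SingleCellDataset:
    """Load a cell × gene matrix with the per-cell annotation column."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx_dir":
        mat, barcodes, features = _read_mtx_dir(path)
        annot_file = path / "annotations.tsv"
        if not annot_file.exists():
            raise FileNotFoundError(f"no annotations.tsv under {path}")
        annot = pd.read_csv(annot_file, sep="\t", index_col=0)
        annot.index = annot.index.astype(str)
        if annotation_key not in annot.columns:
            raise KeyError(
                f"annotation key {annotation_key!r} not found; "
                f"available: {list(annot.columns)}")
        labels = annot.loc[barcodes, annotation_key].astype(str).to_numpy()
        return SingleCellDataset(mat, barcodes, features, labels)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        if annotation_key not in df.columns:
            raise KeyError(
                f"annotation key {annotation_key!r} not found; "
                f"available: {[c for c in df.columns if df[c].dtype == object]}")
        labels = df[annotation_key].astype(str).to_numpy()
        expr = df.drop(columns=[annotation_key])
        return SingleCellDataset(expr.to_numpy(dtype=np.float64),
                                 df.index.astype(str).to_numpy(),
                                 expr.columns.astype(str).to_numpy(), labels)
    if fmt == "h5ad":
        import anndata as ad
        adata = ad.read_h5ad(path)
        if annotation_key not in adata.obs.columns:
            raise KeyError(
                f"annotation key {annotation_key!r} not found; "
                f"available: {list(adata.obs.columns)}")
        X = adata.X.toarray() if scipy.sparse.issparse(adata.X) else np.asarray(adata.X)
        return SingleCellDataset(X, adata.obs_names.to_numpy(),
                                 adata.var_names.to_numpy(),
                                 adata.obs[annotation_key].astype(str).to_numpy())
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "mtx_dir"
    if path.suffix == ".h5ad":
        return "h5ad"
    return "csv"


def select_hvgs(ds, n_top):
    """Subset to the ``n_top`` most variable genes (or ``"all"``).

    Ranking is seurat-flavor normalized dispersion on log1p
    library-size-normalized counts. Selected genes keep their original
    relative order, which makes the operation idempotent for fixed n_top.
    """
    if n_top == "all":
        return ds
    n_top = int(n_top)
    if n_top <= 0:
        raise ValueError("n_top must be positive or 'all'")
    if n_top >= ds.n_genes:
        return ds
    import scanpy as sc
    import anndata as ad
    adata = ad.AnnData(X=np.asarray(ds.expression, dtype=np.float64).copy())
    adata.var_names = [str(g) for g in ds.gene_ids]
    sc.pp.normalize_total(adata)
    sc.pp.log1p(adata)
    sc.pp.highly_variable_genes(adata, flavor="seurat")
    # take exactly n_top by rank (binned z-score, then raw dispersion, then
    # index) — the boolean cutoff column can tie at small gene counts
    dnorm = np.nan_to_num(adata.var["dispersions_norm"].to_numpy(), nan=-np.inf)
    disp = np.nan_to_num(adata.var["dispersions"].to_numpy(), nan=-np.inf)
    order = np.lexsort((np.arange(ds.n_genes), -disp, -dnorm))
    chosen = np.zeros(ds.n_genes, dtype=bool)
    chosen[order[:n_top]] = True
    keep = [g for g, hv in zip(ds.gene_ids, chosen) if hv]
    return ds.subset_genes(keep)


def harmonize_genes(st: SpatialDataset, sc: SingleCellDataset):
    """Restrict both datasets to the shared gene set, lexicographically sorted."""
    common = sorted(set(st.gene_ids) & set(sc.gene_ids))
    if not common:
        raise ValueError("no genes shared between the ST and scRNA-seq datasets")
    return st.subset_genes(common), sc.subset_genes(common)


def build_annotation_matrix(sc: SingleCellDataset) -> AnnotationMatrix:
    """One-hot encode the per-cell annotations; labels sorted alphabetically."""
    labels = np.array(sorted(set(map(str, sc.annotations))), dtype=object)
    col = {lab: j for j, lab in enumerate(labels)}
    S = np.zeros((sc.n_cells, len(labels)))
    for i, a in enumerate(sc.annotations):
        S[i, col[str(a)]] = 1.0
    return AnnotationMatrix(S, labels)


def normalize_expression(X: np.ndarray, target_sum: float | None = None) -> np.ndarray:
    """Library-size normalize rows to ``target_sum`` (default: median total),
    then log1p. Zero rows pass through as zeros."""
    X = np.asarray(X, dtype=np.float64)
    totals = X.sum(axis=1)
    if target_sum is None:
        pos = totals[totals > 0]
        target_sum = float(np.median(pos)) if pos.size else 1.0
    scale = np.divide(target_sum, totals, out=np.ones_like(totals),
                      where=totals > 0)
    return np.log1p(X * scale[:, None])


def standardize_genes(X: np.ndarray) -> np.ndarray:
    """Per-gene z-score (columns to mean 0, variance 1; constant genes to 0).

    Centering removes the per-gene baseline that otherwise dominates both the
    autoencoder objective and the expression-matching term of the mapping
    loss; unit scaling gives marker genes the same weight as high-abundance
    housekeeping genes.
    """
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


# ------------------------------------------------------------------ writers

def write_spatial(ds: SpatialDataset, out_dir, format: str = "mtx_dir") -> Path:
    out_dir = Path(out_dir)
    if format == "mtx_dir":
        out_dir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(out_dir / "matrix.mtx"),
                         scipy.sparse.coo_matrix(ds.expression.T))
        _write_ids(out_dir / "features.tsv", ds.gene_ids)
        _write_ids(out_dir / "barcodes.tsv", ds.spot_ids)
        pd.DataFrame({"x": ds.coordinates[:, 0], "y": ds.coordinates[:, 1]},
                     index=pd.Index(ds.spot_ids, name="spot_id")).to_csv(
            out_dir / "coordinates.tsv", sep="\t")
        return out_dir
    if format == "csv":
        out_dir.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(ds.expression, index=pd.Index(ds.spot_ids, name="spot_id"),
                          columns=ds.gene_ids)
        df.insert(0, "x", ds.coordinates[:, 0])
        df.insert(1, "y", ds.coordinates[:, 1])
        df.to_csv(out_dir)
        return out_dir
    raise ValueError(f"unknown format {format!r}")


def write_single_cell(sc: SingleCellDataset, out_dir, format: str = "mtx_dir",
                      annotation_key: str = "cell_type") -> Path:
    out_dir = Path(out_dir)
    if format == "mtx_dir":
        out_dir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(out_dir / "matrix.mtx"),
                         scipy.sparse.coo_matrix(sc.expression.T))
        _write_ids(out_dir / "features.tsv", sc.gene_ids)
        _write_ids(out_dir / "barcodes.tsv", sc.cell_ids)
        pd.DataFrame({annotation_key: sc.annotations},
                     index=pd.Index(sc.cell_ids, name="cell_id")).to_csv(
            out_dir / "annotations.tsv", sep="\t")
        return out_dir
    if format == "csv":
        out_dir.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(sc.expression, index=pd.Index(sc.cell_ids, name="cell_id"),
                          columns=sc.gene_ids)
        df.insert(0, annotation_key, sc.annotations)
        df.to_csv(out_dir)
        return out_dir
    raise ValueError(f"unknown format {format!r}")


def _write_ids(path: Path, ids) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")
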