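"""Readers and writers for the on-disk formats the pipeline exchanges.

Single-cell matrices travel either as a 10x-style MatrixMarket triplet
(``matrix.mtx`` genes×cells, ``genes.tsv``, ``barcodes.tsv``) or as a dense
cells×genes CSV; cohort expression, survival and label tables are plain CSV.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_10x_mtx",
    "write_10x_mtx",
    "read_dense_csv",
    "write_dense_csv",
    "read_counts",
    "read_survival_csv",
    "write_survival_csv",
]


def _open_any(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find(outdir: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = outdir / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {outdir}")


def read_10x_mtx(path) -> ad.AnnData:
    """Read a 10x triplet directory into cells×genes AnnData (MTX is genes×cells)."""
    outdir = Path(path)
    with _open_any(_find(outdir, "matrix.mtx"), "rb") as fh:
        mat = spio.mmread(fh).tocsr()
    genes = pd.read_csv(_find(outdir, "genes.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(_find(outdir, "barcodes.tsv"), sep="\t", header=None)
    gene_ids = genes.iloc[:, 0].astype(str).to_numpy()
    cell_ids = barcodes.iloc[:, 0].astype(str).to_numpy()
    X = mat.T.tocsr()
    if X.shape != (len(cell_ids), len(gene_ids)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(gene_ids)} genes x "
            f"{len(cell_ids)} barcodes"
        )
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=cell_ids), var=pd.DataFrame(index=gene_ids))
    if genes.shape[1] > 1:
        adata.var["gene_symbol"] = genes.iloc[:, 1].astype(str).to_numpy()
    return adata


def write_10x_mtx(adata: ad.AnnData, path, gzipped: bool = False) -> None:
    """Write cells×genes AnnData as a 10x triplet (matrix stored genes×cells)."""
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    with _open_any(outdir / f"matrix.mtx{suffix}", "wb") as fh:
        spio.mmwrite(fh, X.T.tocoo(), field="integer" if X.dtype.kind in "iu" else "real")
    symbols = adata.var.get("gene_symbol", pd.Series(adata.var_names, index=adata.var_names))
    genes = pd.DataFrame({"id": adata.var_names, "symbol": np.asarray(symbols)})
    with _open_any(outdir / f"genes.tsv{suffix}", "wt") as fh:
        genes.to_csv(fh, sep="\t", header=False, index=False)
    with _open_any(outdir / f"barcodes.tsv{suffix}", "wt") as fh:
        pd.Series(adata.obs_names).to_csv(fh, sep="\t", header=False, index=False)


def read_dense_csv(path) -> ad.AnnData:
    """Read a dense cells×genes CSV (first column = cell ids) into AnnData."""
    df = pd.read_csv(path, index_col=0)
    label_cols = [c for c in df.columns if c.lower() in {"cluster", "label", "true_cluster"}]
    obs = pd.DataFrame(index=df.index.astype(str))
    for c in label_cols:
        obs[c] = df.pop(c).to_numpy()
    X = sparse.csr_matrix(df.to_numpy())
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=df.columns.astype(str)))


def write_dense_csv(adata: ad.AnnData, path) -> None:
    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
    pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names).to_csv(path)


def read_counts(path) -> ad.AnnData:
    """Dispatch: directory → 10x triplet, file → dense CSV."""
    p = Path(path)
    return read_10x_mtx(p) if p.is_dir() else read_dense_csv(p)


def read_survival_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table lacks columns: {sorted(missing)}")
    return df


def write_survival_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
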