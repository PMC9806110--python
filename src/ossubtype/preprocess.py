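"""Quality control, normalization, variable-gene selection and clustering.

The QC contract is fixed and order-dependent: genes are filtered first
(detected in at least ``min_cells_per_gene`` cells), then cells are filtered
on metrics computed over the retained genes (detected-gene count within
``[min_genes, max_genes]``, mitochondrial fraction at most ``max_mito_frac``,
and an explicitly-mode-switched ribosomal rule).  Normalization is the
library-size log transform ``ln(1 + count / cell_total * scale_factor)``.
Variable genes use the clipped standardized-variance ("vst") statistic;
clustering is PCA + k-means with a fixed seed, which gives the downstream
classification the cluster labels it needs without a neighbor-graph
dependency.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .exceptions import ConfigurationError, EmptyResultError

__all__ = [
    "flag_genes",
    "qc_metrics",
    "filter_cells_genes",
    "lognormalize",
    "select_variable_genes",
    "embed_and_cluster",
    "ari",
    "cluster_fractions",
]

MITO_PREFIXES = ("MT-", "mt-", "Mt-")
RIBO_PREFIXES = ("RPS", "RPL", "Rps", "Rpl")


def flag_genes(
    adata: ad.AnnData,
    mito_prefixes: Sequence[str] = MITO_PREFIXES,
    ribo_prefixes: Sequence[str] = RIBO_PREFIXES,
) -> ad.AnnData:
    """Annotate ``var`` with ``is_mitochondrial`` / ``is_ribosomal`` by gene-name prefix.

    Existing flag columns are kept untouched, so callers may pre-set them.
    """
    names = adata.var_names.astype(str)
    if "is_mitochondrial" not in adata.var:
        adata.var["is_mitochondrial"] = names.str.startswith(tuple(mito_prefixes))
    if "is_ribosomal" not in adata.var:
        adata.var["is_ribosomal"] = names.str.startswith(tuple(ribo_prefixes))
    return adata


def _row_totals(X) -> np.ndarray:
    return np.asarray(X.sum(axis=1)).ravel()


def qc_metrics(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell totals, detected-gene counts and mito/ribo count fractions."""
    flag_genes(adata)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    totals = _row_totals(X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito = np.where(totals > 0, _row_totals(X[:, adata.var["is_mitochondrial"].values]) / totals, 0.0)
        ribo = np.where(totals > 0, _row_totals(X[:, adata.var["is_ribosomal"].values]) / totals, 0.0)
    return pd.DataFrame(
        {"total_counts": totals, "n_genes_detected": n_genes, "mito_frac": mito, "ribo_frac": ribo},
        index=adata.obs_names,
    )


def filter_cells_genes(
    adata: ad.AnnData,
    min_cells_per_gene: int = 3,
    max_mito_frac: float = 0.20,
    ribo_rule: str = "off",
    ribo_frac_cut: float = 0.05,
    min_genes: int = 200,
    max_genes: int = 5000,
) -> ad.AnnData:
    """Apply the fixed genes-then-cells QC filter, returning a new matrix.

    Genes must be detected (count > 0) in at least ``min_cells_per_gene``
    cells of the input.  Cells are then judged on the gene-filtered matrix:
    kept iff ``min_genes <= detected genes <= max_genes``, mitochondrial
    fraction ``<= max_mito_frac``, and the ribosomal rule passes.
    ``ribo_rule`` is one of ``off``, ``remove_below`` (drop cells with
    ribosomal fraction < cut) or ``remove_above`` (drop cells with fraction
    > cut) — the direction is a mode, not a guess.  A removal report is
    attached as ``.uns['qc_report']``.

    Raises :class:`EmptyResultError` with diagnostic counts if no gene or no
    cell survives.
    """
    if min_cells_per_gene < 0 or min_genes < 0 or max_genes < 0 or max_mito_frac < 0:
        raise ConfigurationError("thresholds must be non-negative")
    if min_genes >= max_genes:
        raise ConfigurationError("min_genes must be < max_genes")
    if ribo_rule not in {"off", "remove_below", "remove_above"}:
        raise ConfigurationError(f"unknown ribo_rule {ribo_rule!r}")

    flag_genes(adata)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)

    cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    gene_keep = cells_per_gene >= min_cells_per_gene
    report = {
        "params": {
            "min_cells_per_gene": min_cells_per_gene,
            "max_mito_frac": max_mito_frac,
            "ribo_rule": ribo_rule,
            "ribo_frac_cut": ribo_frac_cut,
            "min_genes": min_genes,
            "max_genes": max_genes,
        },
        "n_genes_in": adata.n_vars,
        "n_cells_in": adata.n_obs,
        "genes_removed_low_detection": int((~gene_keep).sum()),
    }
    if not gene_keep.any():
        raise EmptyResultError("all genes removed by detection filter", report)

    sub = adata[:, gene_keep]
    metrics = qc_metrics(sub.copy())
    ok_genes = (metrics["n_genes_detected"] >= min_genes) & (metrics["n_genes_detected"] <= max_genes)
    ok_mito = metrics["mito_frac"] <= max_mito_frac
    if ribo_rule == "remove_below":
        ok_ribo = metrics["ribo_frac"] >= ribo_frac_cut
    elif ribo_rule == "remove_above":
        ok_ribo = metrics["ribo_frac"] <= ribo_frac_cut
    else:
        ok_ribo = pd.Series(True, index=metrics.index)
    cell_keep = (ok_genes & ok_mito & ok_ribo).to_numpy()

    report.update(
        cells_removed_gene_count=int((~ok_genes).sum()),
        cells_removed_mito=int((~ok_mito).sum()),
        cells_removed_ribo=int((~ok_ribo).sum()),
        cells_removed_total=int((~cell_keep).sum()),
        n_genes_out=int(gene_keep.sum()),
        n_cells_out=int(cell_keep.sum()),
    )
    if not cell_keep.any():
        raise EmptyResultError("all cells removed by QC filters", report)

    out = adata[cell_keep, gene_keep].copy()
    out.uns["qc_report"] = report
    out.obs = out.obs.drop(columns=metrics.columns, errors="ignore").join(metrics.loc[cell_keep])
    return out


def lognormalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size normalize: entry = ln(1 + count / cell_total * scale_factor)."""
    if scale_factor <= 0:
        raise ConfigurationError("scale_factor must be > 0")
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    totals = _row_totals(X)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cannot normalize cells with zero total counts: {list(adata.obs_names[zero[:5]])}"
        )
    norm = X.astype(np.float64).multiply(scale_factor / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out = ad.AnnData(X=norm, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns.update(adata.uns)
    out.uns["normalization"] = {"method": "lognormalize", "scale_factor": scale_factor}
    return out


def select_variable_genes(adata: ad.AnnData, n: int = 1000, chunk: int = 512) -> list[str]:
    """Top-``n`` genes by clipped standardized variance, ties by gene id.

    The statistic is the "vst" convention: per-gene values are standardized by
    the mean–variance-trend expected standard deviation (quadratic fit of
    log10 variance on log10 mean), clipped above at sqrt(n_cells), and the
    variance of the clipped values ranks the genes.  Constant genes score 0
    and can never precede a non-constant gene.
    """
    if n > adata.n_vars:
        raise ValueError(f"n={n} exceeds the {adata.n_vars} available genes")
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    X = X.tocsc()
    n_cells = adata.n_obs
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n_cells / max(n_cells - 1, 1)
    var = np.maximum(var, 0.0)
    pos = var > 0

    exp_sd = np.ones_like(var)
    if pos.sum() >= 3:
        coef = np.polyfit(np.log10(mean[pos]), np.log10(var[pos]), deg=2)
        exp_sd[pos] = np.sqrt(10 ** np.polyval(coef, np.log10(mean[pos])))
    else:  # too few informative genes for a trend: standardize by own sd
        exp_sd[pos] = np.sqrt(var[pos])

    clip = np.sqrt(n_cells)
    stat = np.zeros_like(var)
    idx_pos = np.flatnonzero(pos)
    for start in range(0, idx_pos.size, chunk):
        cols = idx_pos[start : start + chunk]
        block = np.asarray(X[:, cols].todense())
        z = (block - mean[cols]) / exp_sd[cols]
        np.minimum(z, clip, out=z)
        stat[cols] = z.var(axis=0, ddof=1)

    order = sorted(range(adata.n_vars), key=lambda i: (-stat[i], str(adata.var_names[i])))
    return [str(adata.var_names[i]) for i in order[:n]]


def embed_and_cluster(
    adata: ad.AnnData,
    genes: Iterable[str],
    n_pcs: int = 30,
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """PCA + k-means cell labels in ``0..k-1``, deterministic given ``seed``.

    Selected genes are z-scored across cells before the PCA.  ``k = 1`` is
    accepted but flagged with a warning (one label, no structure recovered).
    """
    genes = list(genes)
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > adata.n_obs:
        raise ConfigurationError(f"k={k} exceeds the {adata.n_obs} cells")
    if n_pcs > min(adata.n_obs, len(genes)):
        raise ConfigurationError("n_pcs must be <= min(n_cells, n_genes)")
    if k == 1:
        warnings.warn("k=1 yields a single cluster; label recovery is undefined")
        return np.zeros(adata.n_obs, dtype=int)
    sub = adata[:, genes].X
    M = sub.toarray() if sparse.issparse(sub) else np.asarray(sub, dtype=float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (M - mu) / sd
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(Z)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**32))
    return km.fit_predict(pcs).astype(int)


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (chance-corrected agreement)."""
    return float(adjusted_rand_score(np.asarray(labels_a), np.asarray(labels_b)))


def cluster_fractions(labels_or_counts) -> pd.Series:
    """Percentage of cells per cluster, from a label vector or a {label: count} map.

    E.g. a cluster holding 369 of 45 238 cells contributes 0.82 (percent,
    two decimals) to the returned series.
    """
    if isinstance(labels_or_counts, Mapping):
        counts = pd.Series(labels_or_counts, dtype=float)
    else:
        counts = pd.Series(labels_or_counts).value_counts().astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no cells to summarize")
    return (100.0 * counts / total).sort_index()
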