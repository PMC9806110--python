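"""One-vs-rest rank-sum marker statistics and exclusive panel selection.

Each cluster is screened against all remaining cells with the two-sided
Wilcoxon rank-sum (Mann–Whitney) test — exact enumeration for small untied
samples, otherwise the normal approximation with tie and continuity
corrections.  The effect size is the natural-log fold change of
count-scale means restored with ``expm1`` and a pseudocount of 1.

Panel selection operationalizes "most specific": a gene enters a subtype's
panel when it passes the q-value / effect / detection-fraction thresholds
for that subtype's terminal cluster, and any gene qualifying for two or more
clusters is removed from all panels (exclusivity), which reproduces the
near-disjointness of the published per-branch marker sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptyPanelError

__all__ = [
    "MarkerPanel",
    "wilcoxon_one_vs_rest",
    "wilcoxon_pairwise",
    "bh_adjust",
    "select_specific_panel",
    "DEFAULT_SELECTION",
]

DEFAULT_SELECTION = {
    "q_max": 0.05,
    "min_effect": float(np.log(1.5)),
    "min_pct_in": 0.25,
    "max_pct_out": 0.25,
}


@dataclass
class MarkerPanel:
    """Named, pairwise-disjoint marker gene sets per subtype group."""

    panels: dict[str, list[str]]
    selection_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.panels = {g: list(v) for g, v in self.panels.items()}
        seen: dict[str, str] = {}
        for grp, genes in self.panels.items():
            if len(genes) == 0:
                raise EmptyPanelError(f"panel for group {grp!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"panel for group {grp!r} has duplicate genes")
            for gene in genes:
                if gene in seen:
                    raise ValueError(
                        f"gene {gene!r} appears in panels {seen[gene]!r} and {grp!r}"
                    )
                seen[gene] = grp

    @property
    def groups(self) -> list[str]:
        return sorted(self.panels)

    @property
    def sizes(self) -> dict[str, int]:
        return {g: len(v) for g, v in self.panels.items()}

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.panels.values())

    def genes(self) -> list[str]:
        return [g for grp in self.groups for g in self.panels[grp]]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"panels": self.panels, "selection_params": self.selection_params}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(panels=d["panels"], selection_params=d.get("selection_params", {}))


def _dense(adata: ad.AnnData, mask: np.ndarray) -> np.ndarray:
    sub = adata.X[mask]
    return sub.toarray() if sparse.issparse(sub) else np.asarray(sub, dtype=float)


def _resolve_labels(adata: ad.AnnData, labels) -> np.ndarray:
    if isinstance(labels, str):
        return np.asarray(adata.obs[labels])
    labels = np.asarray(labels)
    if labels.shape[0] != adata.n_obs:
        raise ValueError("labels length does not match the number of cells")
    return labels


def _rank_sum_table(x_in: np.ndarray, x_out: np.ndarray, method: str) -> np.ndarray:
    """Two-sided Mann–Whitney p per gene column of two dense blocks."""
    n_in, n_out = x_in.shape[0], x_out.shape[0]
    small = n_in <= 10 and n_out <= 10
    if method == "exact" or (method == "auto" and small):
        pvals = np.empty(x_in.shape[1])
        for j in range(x_in.shape[1]):
            col = np.concatenate([x_in[:, j], x_out[:, j]])
            tied = np.unique(col).size < col.size
            m = "asymptotic" if tied else "exact"
            pvals[j] = stats.mannwhitneyu(
                x_in[:, j], x_out[:, j], alternative="two-sided", method=m
            ).pvalue
        return np.minimum(pvals, 1.0)
    res = stats.mannwhitneyu(
        x_in, x_out, alternative="two-sided", method="asymptotic", axis=0
    )
    p = np.asarray(res.pvalue, dtype=float)
    # a gene constant across all cells has zero rank variance: no evidence
    both_const = (x_in.max(axis=0) == x_in.min(axis=0)) & (
        x_out.max(axis=0) == x_out.min(axis=0)
    ) & (x_in[0] == x_out[0] if n_in and n_out else True)
    p[~np.isfinite(p)] = 1.0
    p[both_const] = 1.0
    return np.minimum(p, 1.0)


def _stats_frame(x_in, x_out, gene_ids, cluster, method) -> pd.DataFrame:
    p = _rank_sum_table(x_in, x_out, method)
    mean_in = np.expm1(x_in).mean(axis=0)
    mean_out = np.expm1(x_out).mean(axis=0)
    effect = np.log((mean_in + 1.0) / (mean_out + 1.0))
    out = pd.DataFrame(
        {
            "gene": gene_ids,
            "cluster": cluster,
            "effect": effect,
            "p_value": p,
            "q_value": bh_adjust(p),
            "pct_in": (x_in > 0).mean(axis=0),
            "pct_out": (x_out > 0).mean(axis=0),
        }
    )
    return out


def wilcoxon_one_vs_rest(
    adata: ad.AnnData, labels, cluster, method: str = "auto"
) -> pd.DataFrame:
    """Rank-sum marker statistics for ``cluster`` against all other cells.

    Returns one row per gene: effect (ln fold change of expm1-restored means,
    pseudocount 1), two-sided p, BH q, and detection fractions in/out of the
    cluster.  ``method`` is ``auto`` (exact for <=10 vs <=10 untied samples,
    else normal approximation), ``exact`` or ``asymptotic``.
    """
    lab = _resolve_labels(adata, labels)
    mask = lab == cluster
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError(
            f"cluster {cluster!r} needs >= 3 cells both inside ({int(mask.sum())}) "
            f"and outside ({int((~mask).sum())})"
        )
    x_in, x_out = _dense(adata, mask), _dense(adata, ~mask)
    return _stats_frame(x_in, x_out, np.asarray(adata.var_names), cluster, method)


def wilcoxon_pairwise(
    adata: ad.AnnData, labels, cluster_a, cluster_b, method: str = "auto"
) -> pd.DataFrame:
    """Rank-sum statistics for ``cluster_a`` against ``cluster_b`` only."""
    lab = _resolve_labels(adata, labels)
    mask_a, mask_b = lab == cluster_a, lab == cluster_b
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError(f"both {cluster_a!r} and {cluster_b!r} need >= 3 cells")
    return _stats_frame(
        _dense(adata, mask_a), _dense(adata, mask_b), np.asarray(adata.var_names), cluster_a, method
    )


def bh_adjust(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment; Benjamini–Hochberg step-up by default."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none" or p.size == 0:
        return p.copy()
    return multipletests(p, method=method)[1]


def select_specific_panel(
    stats_by_group: Mapping[str, pd.DataFrame],
    q_max: float = DEFAULT_SELECTION["q_max"],
    min_effect: float = DEFAULT_SELECTION["min_effect"],
    min_pct_in: float = DEFAULT_SELECTION["min_pct_in"],
    max_pct_out: float = DEFAULT_SELECTION["max_pct_out"],
) -> MarkerPanel:
    """Build exclusive per-group marker panels from per-cluster statistics.

    ``stats_by_group`` maps each subtype group (e.g. ``A``/``B``/``C``) to the
    one-vs-rest statistics of its terminal cluster.  Candidates pass
    ``q <= q_max``, ``effect >= min_effect``, ``pct_in >= min_pct_in`` and
    ``pct_out <= max_pct_out``; any gene qualifying for two or more groups is
    dropped from every panel; survivors are ranked by effect descending
    (ties by gene id).  Panel sizes may differ across groups.
    """
    candidates: dict[str, pd.DataFrame] = {}
    for grp, df in stats_by_group.items():
        sel = df[
            (df["q_value"] <= q_max)
            & (df["effect"] >= min_effect)
            & (df["pct_in"] >= min_pct_in)
            & (df["pct_out"] <= max_pct_out)
        ]
        candidates[grp] = sel
    counts: dict[str, int] = {}
    for sel in candidates.values():
        for gene in sel["gene"]:
            counts[gene] = counts.get(gene, 0) + 1
    shared = {g for g, c in counts.items() if c >= 2}

    params = {
        "q_max": q_max,
        "min_effect": min_effect,
        "min_pct_in": min_pct_in,
        "max_pct_out": max_pct_out,
        "excluded_shared_genes": sorted(shared),
    }
    panels: dict[str, list[str]] = {}
    for grp, sel in candidates.items():
        keep = sel[~sel["gene"].isin(shared)]
        keep = keep.sort_values(["effect", "gene"], ascending=[False, True])
        panels[grp] = list(keep["gene"])
        if not panels[grp]:
            raise EmptyPanelError(
                f"no marker survives selection for group {grp!r} "
                f"(q_max={q_max}, min_effect={min_effect:.3g}); relax the thresholds"
            )
    return MarkerPanel(panels=panels, selection_params=params)
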