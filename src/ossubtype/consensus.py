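"""Resampling consensus clustering of bulk cohorts on marker-panel genes.

:class:`ConsensusSubtyper` is the model object: it holds the cohort
expression restricted to panel genes plus the resampling protocol
(80% sample subsampling, k-means inner clusterer with 10 restarts on
per-gene z-scored expression, a range of candidate k).  ``fit(seed)``
returns a :class:`ConsensusClusteringResult` carrying, for every k, the
consensus matrix (pairwise co-clustering frequency among co-drawn
resamples), final labels from average-linkage hierarchical clustering of
``1 - consensus``, the off-diagonal consensus CDF and the PAC score
(proportion of ambiguous clustering — consensus mass strictly between the
lower and upper confidence bands; low PAC marks a stable k).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .exceptions import ConfigurationError, GroupNamingError
from .markers import MarkerPanel

__all__ = [
    "ConsensusSubtyper",
    "ConsensusClusteringResult",
    "CDFCurve",
    "make_resample_plan",
    "pac_and_cdf",
    "assign_from_consensus",
]

logger = logging.getLogger(__name__)

_PLAN_STREAM = 97  # entropy offset separating the resampling stream from user seeds


def make_resample_plan(
    seed: int, n_samples: int, n_resamples: int, subsample_frac: float
) -> list[tuple[np.ndarray, int]]:
    """Deterministic list of (sorted sample indices, inner-clusterer seed).

    Public so a replay oracle can re-derive the exact draws used by
    :meth:`ConsensusSubtyper.fit`.
    """
    if not 0 < subsample_frac <= 1:
        raise ConfigurationError("subsample_frac must be in (0, 1]")
    if n_resamples < 1:
        raise ConfigurationError("n_resamples must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), _PLAN_STREAM)))
    size = int(np.ceil(subsample_frac * n_samples))
    plan = []
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n_samples, size=size, replace=False))
        plan.append((idx, int(rng.integers(2**31))))
    return plan


class CDFCurve(NamedTuple):
    """Empirical CDF of the off-diagonal consensus entries."""

    points: np.ndarray  # sorted off-diagonal entries
    probs: np.ndarray  # ECDF evaluated at each point

    def __call__(self, x: float) -> float:
        return float(np.mean(self.points <= x)) if self.points.size else 0.0


def pac_and_cdf(
    consensus_matrix, lower: float = 0.1, upper: float = 0.9
) -> tuple[CDFCurve, float]:
    """Off-diagonal consensus CDF and PAC = CDF(upper) − CDF(lower)."""
    if lower >= upper:
        raise ConfigurationError("lower must be < upper")
    M = np.asarray(consensus_matrix, dtype=float)
    iu = np.triu_indices(M.shape[0], k=1)
    entries = np.sort(M[iu])
    probs = np.arange(1, entries.size + 1) / max(entries.size, 1)
    cdf = CDFCurve(entries, probs)
    pac = cdf(upper) - cdf(lower)
    return cdf, pac


@dataclass
class ConsensusClusteringResult:
    """Fitted consensus-clustering output; see :class:`ConsensusSubtyper`."""

    sample_ids: list[str]
    gene_ids: list[str]
    k_range: list[int]
    indicator_counts: np.ndarray
    cocluster_counts: dict[int, np.ndarray]
    consensus_per_k: dict[int, np.ndarray]
    labels_per_k: dict[int, np.ndarray]
    cdf_per_k: dict[int, CDFCurve]
    pac_per_k: dict[int, float]
    chosen_k: int
    undefined_pairs: np.ndarray
    panel: MarkerPanel | None = None
    panel_scores: pd.DataFrame | None = None
    protocol: dict = field(default_factory=dict)

    def consensus_matrix(self, k: int | None = None) -> pd.DataFrame:
        k = self.chosen_k if k is None else k
        return pd.DataFrame(self.consensus_per_k[k], index=self.sample_ids, columns=self.sample_ids)

    def labels(self, k: int | None = None) -> pd.Series:
        k = self.chosen_k if k is None else k
        return pd.Series(self.labels_per_k[k], index=self.sample_ids, name=f"cluster_k{k}")

    def assign_groups(self, k: int | None = None) -> pd.Series:
        """Name each consensus cluster by the subtype panel it overexpresses.

        Every cluster maps to the group whose panel-mean z-score is highest
        among its samples; two clusters claiming the same group raise
        :class:`GroupNamingError`.  ``k = 1`` is flagged and left unnamed.
        """
        k = self.chosen_k if k is None else k
        if k == 1:
            warnings.warn("k=1: a single cluster cannot be named; returning 'ungrouped'")
            return pd.Series("ungrouped", index=self.sample_ids, name="group")
        if self.panel_scores is None:
            raise GroupNamingError("no marker panel attached; cannot name clusters")
        labels = self.labels(k)
        mapping: dict[int, str] = {}
        for cl in sorted(labels.unique()):
            means = self.panel_scores.loc[labels[labels == cl].index].mean(axis=0)
            grp = means.sort_index().idxmax()
            if grp in mapping.values():
                raise GroupNamingError(
                    f"clusters {[c for c, g in mapping.items() if g == grp][0]} and {cl} "
                    f"both map to group {grp!r}"
                )
            mapping[cl] = grp
        return labels.map(mapping).rename("group")

    def summary(self) -> str:
        lines = [
            "Consensus clustering result",
            f"  samples: {len(self.sample_ids)}   panel genes: {len(self.gene_ids)}",
            f"  resamples: {self.protocol.get('n_resamples')}  "
            f"subsample fraction: {self.protocol.get('subsample_frac')}",
            "  k    PAC      cluster sizes",
        ]
        for k in self.k_range:
            sizes = [int(x) for x in np.bincount(self.labels_per_k[k], minlength=k)]
            star = " *" if k == self.chosen_k else ""
            lines.append(f"  {k:<4d} {self.pac_per_k[k]:<8.4f} {sizes}{star}")
        lines.append(f"  chosen k (argmin PAC): {self.chosen_k}")
        return "\n".join(lines)

    def plot_consensus(self, k: int | None = None, ax=None):
        """Heatmap of the consensus matrix, samples ordered by cluster label."""
        import matplotlib.pyplot as plt

        k = self.chosen_k if k is None else k
        order = np.argsort(self.labels_per_k[k], kind="stable")
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        im = ax.imshow(self.consensus_per_k[k][np.ix_(order, order)], vmin=0, vmax=1, cmap="Blues")
        ax.set_title(f"Consensus matrix (k={k}, PAC={self.pac_per_k[k]:.3f})")
        ax.figure.colorbar(im, ax=ax, shrink=0.8)
        return ax


class ConsensusSubtyper:
    """Resampling consensus clustering model over a bulk cohort.

    Parameters
    ----------
    expr : samples×genes DataFrame (FPKM-like continuous values).
    panel : MarkerPanel restricting the feature space; panel genes missing
        from ``expr`` are logged and dropped.  A plain gene list may be
        passed instead (group naming is then unavailable).
    k_range : candidate cluster numbers (default 2..6).
    n_resamples, subsample_frac : resampling protocol (default 500 × 80%).
    inner_n_init : k-means restarts per inner run.
    zscore : per-gene z-scoring across the cohort before clustering
        (default on; FPKM-scale genes otherwise dominate the distances).
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        panel: MarkerPanel | Sequence[str],
        k_range: Iterable[int] = range(2, 7),
        n_resamples: int = 500,
        subsample_frac: float = 0.8,
        inner_n_init: int = 10,
        zscore: bool = True,
    ):
        self.k_range = sorted(int(k) for k in k_range)
        if not self.k_range or self.k_range[0] < 1:
            raise ConfigurationError("k_range must contain integers >= 1")
        if isinstance(panel, MarkerPanel):
            self.panel, genes = panel, panel.genes()
        else:
            self.panel, genes = None, list(panel)
        missing = [g for g in genes if g not in expr.columns]
        if missing:
            logger.warning("dropping %d panel genes absent from expression: %s",
                           len(missing), missing[:10])
        self.gene_ids = [g for g in genes if g in expr.columns]
        if not self.gene_ids:
            raise ConfigurationError("no panel gene is present in the expression table")
        self.expr = expr.loc[:, self.gene_ids].astype(float)
        if self.expr.shape[0] < 2 * max(self.k_range):
            raise ConfigurationError(
                f"{self.expr.shape[0]} samples cannot support k up to {max(self.k_range)}"
            )
        self.n_resamples = int(n_resamples)
        self.subsample_frac = float(subsample_frac)
        self.inner_n_init = int(inner_n_init)
        self.zscore = bool(zscore)

    def _standardized(self) -> np.ndarray:
        M = self.expr.to_numpy()
        if not self.zscore:
            return M
        mu, sd = M.mean(axis=0), M.std(axis=0)
        sd[sd == 0] = 1.0
        return (M - mu) / sd

    def fit(self, seed: int = 0) -> ConsensusClusteringResult:
        Z = self._standardized()
        n = Z.shape[0]
        plan = make_resample_plan(seed, n, self.n_resamples, self.subsample_frac)

        indicator = np.zeros((n, n), dtype=np.int64)
        cocluster = {k: np.zeros((n, n), dtype=np.int64) for k in self.k_range}
        for idx, inner_seed in plan:
            indicator[np.ix_(idx, idx)] += 1
            sub = Z[idx]
            for k in self.k_range:
                km = KMeans(n_clusters=k, n_init=self.inner_n_init, random_state=inner_seed)
                lab = km.fit_predict(sub)
                same = (lab[:, None] == lab[None, :]).astype(np.int64)
                cocluster[k][np.ix_(idx, idx)] += same

        undefined = indicator == 0
        np.fill_diagonal(undefined, False)
        if undefined.any():
            warnings.warn(
                f"{int(undefined.sum()) // 2} sample pairs were never co-drawn; "
                "their consensus entries are set to 0"
            )
        consensus, labels_per_k, cdfs, pacs = {}, {}, {}, {}
        for k in self.k_range:
            with np.errstate(invalid="ignore", divide="ignore"):
                C = np.where(indicator > 0, cocluster[k] / np.maximum(indicator, 1), 0.0)
            np.fill_diagonal(C, 1.0)
            consensus[k] = C
            if k == 1:
                labels_per_k[k] = np.zeros(n, dtype=int)
            else:
                link = linkage(squareform(1.0 - C, checks=False), method="average")
                labels_per_k[k] = (fcluster(link, t=k, criterion="maxclust") - 1).astype(int)
            cdfs[k], pacs[k] = pac_and_cdf(C)

        chosen_k = min(self.k_range, key=lambda k: (pacs[k], k))
        panel_scores = None
        if self.panel is not None:
            cols = {}
            Zdf = pd.DataFrame(Z, index=self.expr.index, columns=self.gene_ids)
            for grp in self.panel.groups:
                present = [g for g in self.panel.panels[grp] if g in Zdf.columns]
                if present:
                    cols[grp] = Zdf[present].mean(axis=1)
            panel_scores = pd.DataFrame(cols)
        return ConsensusClusteringResult(
            sample_ids=list(self.expr.index.astype(str)),
            gene_ids=self.gene_ids,
            k_range=self.k_range,
            indicator_counts=indicator,
            cocluster_counts=cocluster,
            consensus_per_k=consensus,
            labels_per_k=labels_per_k,
            cdf_per_k=cdfs,
            pac_per_k=pacs,
            chosen_k=chosen_k,
            undefined_pairs=undefined,
            panel=self.panel,
            panel_scores=panel_scores,
            protocol={
                "n_resamples": self.n_resamples,
                "subsample_frac": self.subsample_frac,
                "inner": "kmeans",
                "inner_n_init": self.inner_n_init,
                "zscore": self.zscore,
                "seed": int(seed),
            },
        )


def assign_from_consensus(result: ConsensusClusteringResult, k: int | None = None) -> pd.Series:
    """Functional wrapper around :meth:`ConsensusClusteringResult.assign_groups`."""
    return result.assign_groups(k)
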