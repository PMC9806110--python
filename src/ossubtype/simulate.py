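"""Synthetic data generator for the subtyping pipeline.

Emulates the three input shapes the analysis consumes:

* a single-cell count matrix with a cancer-stem-cell-like (CSC) root cluster,
  three two-cluster tumor differentiation branches (OS-A1/A2, OS-B1/B2,
  OS-C1/C2) and three normal mesenchymal/immune populations, each cluster
  carrying a planted set of exclusive marker genes;
* a bulk expression cohort in which every sample is dominated by one branch's
  terminal-cluster profile, diluted by a normal-tissue background, with
  exponential survival whose hazard depends on the subtype (the B-like group
  carries the largest hazard, i.e. the worst outcome);
* an IHC-like marker score table with group-specific elevated scores.

Counts follow a negative-binomial model: gene-level baseline means are
log-normal, each cluster multiplies its own planted markers by
``exp(marker_log_fold_change)``, and per-cell expected counts are rescaled so
the expected library size is uniform on ``library_size_range``.  All
randomness derives from a single root seed through fixed per-stage streams,
so partial reruns of any one stage are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import ConfigurationError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_single_cell",
    "simulate_bulk_cohort",
    "simulate_ihc_panel",
    "DEFAULT_CLUSTERS",
    "GROUP_TERMINAL_CLUSTER",
    "NORMAL_CLUSTERS",
]

#: default cluster layout: CSC root, three 2-cluster branches, three normal populations
DEFAULT_CLUSTERS: tuple[tuple[str, int], ...] = (
    ("CSC", 200),
    ("OS-A1", 200),
    ("OS-A2", 200),
    ("OS-B1", 200),
    ("OS-B2", 200),
    ("OS-C1", 200),
    ("OS-C2", 200),
    ("BMSC", 200),
    ("Osteoblast", 200),
    ("Immune", 200),
)

#: terminal cluster whose profile dominates each bulk subtype group
GROUP_TERMINAL_CLUSTER: dict[str, str] = {"A": "OS-A2", "B": "OS-B2", "C": "OS-C2"}

#: non-tumor clusters averaged into the bulk background ("stromal contamination")
NORMAL_CLUSTERS: tuple[str, ...] = ("BMSC", "Osteoblast", "Immune")

# fixed per-stage entropy offsets for seed derivation
_STAGES = {"genes": 11, "sc": 23, "bulk": 37, "ihc": 53}


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Stage-specific generator derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STAGES[stage])))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data model.

    Defaults are desk-scale but comfortably detectable: 2 000 genes with
    20 exclusive markers per cluster at a natural-log fold change of 1.5
    (≈4.5× mean elevation), NB dispersion 0.3, 200 cells per cluster,
    30 bulk samples per subtype at purity 0.7, and a B-group hazard twice
    that of A and C.  Library sizes (900–1 100 counts over 2 000 genes) with
    attenuated marker baselines emulate how lineage-restricted genes behave
    in droplet data on this reduced gene universe: planted markers are
    detected in roughly 20% of cells outside their own cluster and ~55–60%
    inside, while ordinary background genes sit near 35–40% detection.
    """

    n_genes: int = 2000
    n_marker_genes_per_cluster: int = 20
    cluster_spec: tuple[tuple[str, int], ...] = DEFAULT_CLUSTERS
    marker_log_fold_change: float = 1.5
    nb_dispersion: float = 0.3
    baseline_mean: float = 0.5
    baseline_sigma: float = 0.3
    marker_baseline_attenuation: float = 0.45
    marker_baseline_sigma: float = 0.1
    library_size_range: tuple[float, float] = (900.0, 1100.0)
    bulk_n_per_group: int = 30
    bulk_purity: float = 0.7
    bulk_noise_sd: float = 0.2
    hazard_scale_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.1, "B": 0.2, "C": 0.1}
    )
    censoring_rate: float = 0.25
    ihc_base: float = 1.0
    ihc_effect: float = 2.0
    ihc_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        spec = tuple(self.cluster_spec)
        if len(spec) == 0:
            raise ConfigurationError("cluster_spec is empty")
        names = [name for name, _ in spec]
        if len(set(names)) != len(names):
            raise ConfigurationError("cluster names must be unique")
        if any(n < 1 for _, n in spec):
            raise ConfigurationError("every cluster must have at least one cell")
        if self.n_genes < 1 or self.n_marker_genes_per_cluster < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.n_genes < len(spec) * self.n_marker_genes_per_cluster:
            raise ConfigurationError(
                "n_genes too small to plant disjoint marker sets for every cluster"
            )
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be > 0")
        if self.baseline_sigma < 0:
            raise ConfigurationError("baseline_sigma must be >= 0")
        if not 0 < self.marker_baseline_attenuation <= 1:
            raise ConfigurationError("marker_baseline_attenuation must be in (0, 1]")
        if self.marker_baseline_sigma < 0:
            raise ConfigurationError("marker_baseline_sigma must be >= 0")
        if self.marker_log_fold_change < 0:
            raise ConfigurationError("marker_log_fold_change must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("library_size_range must satisfy 0 < min <= max")
        if not 0.0 <= self.bulk_purity <= 1.0:
            raise ConfigurationError("bulk_purity must be in [0, 1]")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigurationError("censoring_rate must be in [0, 1]")
        if self.bulk_noise_sd < 0 or self.ihc_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if self.bulk_n_per_group < 1:
            raise ConfigurationError("bulk_n_per_group must be >= 1")

    @property
    def cluster_names(self) -> list[str]:
        return [name for name, _ in self.cluster_spec]

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside each simulated dataset."""

    cell_labels: dict[str, str] | None = None
    planted_markers: dict[str, list[str]] | None = None
    bulk_group: dict[str, str] | None = None
    true_survival_params: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_model(config: SimulationConfig):
    """Gene ids, baseline means and planted-marker layout (``genes`` stream).

    Returns ``(gene_ids, base_means, markers, rel_profile)`` where
    ``rel_profile`` is a clusters×genes matrix of relative expected expression
    (baseline mean with the cluster's own markers multiplied by exp(lfc)).
    """
    rng = _rng(config.seed, "genes")
    g = config.n_genes
    gene_ids = np.array([f"gene{i:04d}" for i in range(g)])
    # log-normal baselines with E[base] = baseline_mean; only the relative
    # spread matters for counts (library scaling cancels the absolute level)
    s = config.baseline_sigma
    base = rng.lognormal(mean=np.log(config.baseline_mean) - s**2 / 2, sigma=s, size=g)
    perm = rng.permutation(g)
    m = config.n_marker_genes_per_cluster
    markers: dict[str, np.ndarray] = {}
    # lineage markers are a coherent gene class: sparsely detected outside
    # their own cluster (below the background baseline) with a narrower
    # dynamic range than arbitrary background genes
    sm = config.marker_baseline_sigma
    all_marker_idx = perm[: len(config.cluster_spec) * m]
    base[all_marker_idx] = (
        config.marker_baseline_attenuation
        * config.baseline_mean
        * rng.lognormal(mean=-(sm**2) / 2, sigma=sm, size=all_marker_idx.size)
    )
    rel = np.tile(base, (len(config.cluster_spec), 1))
    for ci, (name, _) in enumerate(config.cluster_spec):
        idx = np.sort(perm[ci * m : (ci + 1) * m])
        markers[name] = idx
        rel[ci, idx] *= np.exp(config.marker_log_fold_change)
    return gene_ids, base, markers, rel


def simulate_single_cell(config: SimulationConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Draw a clustered single-cell count matrix.

    Counts are NB with mean ``T_c * rel[cluster] / sum(rel[cluster])`` where
    the target library size ``T_c`` is uniform on ``library_size_range``, and
    variance ``mu + dispersion * mu**2``.  Cluster labels are stored in
    ``obs['true_cluster']`` and, with the planted marker gene lists, in the
    returned :class:`SyntheticTruth`.
    """
    config.validate()
    gene_ids, _, markers, rel = _gene_model(config)
    rng = _rng(config.seed, "sc")
    lo, hi = config.library_size_range
    inv_disp = 1.0 / config.nb_dispersion

    blocks, labels, cell_ids = [], [], []
    cell_no = 0
    for ci, (name, n_cells) in enumerate(config.cluster_spec):
        profile = rel[ci] / rel[ci].sum()
        lib = rng.uniform(lo, hi, size=n_cells)
        mu = lib[:, None] * profile[None, :]
        p = inv_disp / (inv_disp + mu)
        counts = rng.negative_binomial(inv_disp, p)
        blocks.append(sparse.csr_matrix(counts.astype(np.int32)))
        labels.extend([name] * n_cells)
        cell_ids.extend(f"cell{cell_no + j:05d}" for j in range(n_cells))
        cell_no += n_cells

    X = sparse.vstack(blocks, format="csr")
    obs = pd.DataFrame({"true_cluster": pd.Categorical(labels)}, index=cell_ids)
    var = pd.DataFrame(index=gene_ids)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    truth = SyntheticTruth(
        cell_labels=dict(zip(cell_ids, labels)),
        planted_markers={k: list(gene_ids[v]) for k, v in markers.items()},
    )
    return adata, truth


def _bulk_profiles(config: SimulationConfig):
    """Per-group dominant profiles and the normal background, on a common scale."""
    gene_ids, base, _, rel = _gene_model(config)
    names = config.cluster_names
    ref_lib = float(np.mean(config.library_size_range))
    scaled = ref_lib * rel / rel.sum(axis=1, keepdims=True)
    profiles = {}
    for group, cluster in GROUP_TERMINAL_CLUSTER.items():
        if cluster not in names:
            raise ConfigurationError(f"cluster_spec lacks terminal cluster {cluster!r}")
        profiles[group] = scaled[names.index(cluster)]
    normal_idx = [names.index(c) for c in NORMAL_CLUSTERS if c in names]
    if normal_idx:
        background = scaled[normal_idx].mean(axis=0)
    else:  # no normal populations simulated: fall back to the unboosted baseline
        background = ref_lib * base / base.sum()
    return gene_ids, profiles, background


def simulate_bulk_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a bulk cohort with subtype-dependent survival.

    Each sample's expression is ``purity * (dominant branch terminal profile)
    + (1 - purity) * background + N(0, noise_sd)``, clipped at zero.  Survival
    times are exponential with the group's hazard; independent exponential
    censoring is tuned so the expected censored fraction equals
    ``censoring_rate``.

    Returns ``(expression samples×genes, survival table, truth)``.
    """
    config.validate()
    groups = sorted(GROUP_TERMINAL_CLUSTER)
    for grp in groups:
        if grp not in config.hazard_scale_by_group:
            raise ConfigurationError(f"hazard_scale_by_group lacks group {grp!r}")
    gene_ids, profiles, background = _bulk_profiles(config)
    rng = _rng(config.seed, "bulk")

    n = config.bulk_n_per_group
    sample_ids, sample_groups, rows = [], [], []
    for grp in groups:
        mean_expr = config.bulk_purity * profiles[grp] + (1 - config.bulk_purity) * background
        noise = rng.normal(0.0, config.bulk_noise_sd, size=(n, len(gene_ids)))
        rows.append(np.clip(mean_expr[None, :] + noise, 0.0, None))
        start = len(sample_ids)
        sample_ids.extend(f"sample{start + j:03d}" for j in range(n))
        sample_groups.extend([grp] * n)
    expr = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=gene_ids)

    rates = np.array([config.hazard_scale_by_group[g] for g in sample_groups])
    death = rng.exponential(1.0 / rates)
    cr = config.censoring_rate
    if cr == 0:
        censor = np.full_like(death, np.inf)
    elif cr >= 1:
        censor = np.zeros_like(death)
    else:
        c_rates = rates * cr / (1.0 - cr)
        censor = rng.exponential(1.0 / c_rates)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    survival = pd.DataFrame({"sample_id": sample_ids, "time": time, "event": event})

    _, _, markers, _ = _gene_model(config)
    truth = SyntheticTruth(
        bulk_group=dict(zip(sample_ids, sample_groups)),
        planted_markers={k: list(gene_ids[v]) for k, v in markers.items()},
        true_survival_params={
            "hazard_scale_by_group": dict(config.hazard_scale_by_group),
            "censoring_rate": cr,
        },
    )
    return expr, survival, truth


def simulate_ihc_panel(
    config: SimulationConfig,
    panel: "Mapping[str, Sequence[str]] | object",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate an IHC-like marker score table for a fresh sample set.

    ``panel`` is a :class:`~ossubtype.markers.MarkerPanel` or a plain
    ``{group: [marker, ...]}`` mapping with at least one marker per group.
    Markers of a sample's true group score ``base + effect + noise``; all
    others ``base + noise``; scores are clipped at zero.
    """
    config.validate()
    panels = getattr(panel, "panels", panel)
    if not panels or any(len(v) == 0 for v in panels.values()):
        raise ConfigurationError("panel must provide >= 1 marker per group")
    marker_group = {m: grp for grp, ms in panels.items() for m in ms}
    markers = list(marker_group)
    groups = sorted(panels)
    rng = _rng(config.seed, "ihc")

    n = config.bulk_n_per_group
    sample_ids = [f"ihc{i:03d}" for i in range(n * len(groups))]
    sample_groups = [g for g in groups for _ in range(n)]
    effect = np.array(
        [[config.ihc_effect * (marker_group[m] == g) for m in markers] for g in sample_groups]
    )
    scores = config.ihc_base + effect + rng.normal(0.0, config.ihc_noise_sd, size=effect.shape)
    table = pd.DataFrame(np.clip(scores, 0.0, None), index=sample_ids, columns=markers)
    truth = SyntheticTruth(bulk_group=dict(zip(sample_ids, sample_groups)))
    return table, truth
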