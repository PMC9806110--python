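# ossubtype

Molecular subtyping of osteosarcoma expression cohorts from single-cell-derived
marker panels.

Osteosarcoma tumor cells organize into three differentiation branches
(OS-A1→A2, OS-B1→B2, OS-C1→C2) rooted in a cancer-stem-cell-like population.
The terminal cluster of each branch carries a set of exclusively overexpressed
marker genes, and those three panels induce a clinically relevant three-group
classification of bulk tumors: Group B patients show markedly worse overall
survival.  `ossubtype` implements that classification pipeline end to end:

1. **QC + normalization + clustering** of single-cell counts: genes detected in
   ≥ 3 cells; cells with 200–5 000 detected genes and ≤ 20% mitochondrial
   reads; `x = ln(1 + c/total · 10⁴)` normalization; the top 1 000 genes by
   clipped standardized variance; PCA + k-means labels.
2. **Marker discovery**: one-vs-rest two-sided Wilcoxon rank-sum per terminal
   cluster with BH correction; effect size `ln((mean_in+1)/(mean_out+1))` on
   `expm1`-restored means; panels are genes passing
   `q ≤ 0.05, effect ≥ ln 1.5, pct_in ≥ 0.25, pct_out ≤ 0.25`, with any gene
   qualifying for two clusters removed from all (exclusivity).
3. **Consensus subtyping** of a bulk cohort on the panel genes: 500 resamples
   of 80% of samples, k-means at each candidate k, consensus matrix
   `M_ij = #co-clustered / #co-drawn`, final labels by average-linkage
   clustering of `1 − M`, and k selected by the PAC criterion
   `PAC = F(0.9) − F(0.1)` on the off-diagonal consensus CDF.
4. **Single-sample classification**: per-group panel scores (`panel_mean` over
   cohort-standardized expression, or `single_marker` — the strongest
   normalized marker, i.e. the IHC rule with the published six-marker panel
   ALKBH5/TOM1L2 → A, CDK4/LMO7 → B, COL6A3/THBS2 → C) and argmax assignment
   with deterministic tie handling.
5. **Survival**: first-principles Kaplan–Meier product-limit estimator
   `S(t) = Π (1 − d_i/n_i)` and g-sample log-rank test
   `χ² = (O−E)ᵀ V⁻¹ (O−E)` on `g−1` components, plus high/low panel-score
   dichotomization.

A synthetic-data generator (`ossubtype.simulate`) emulates all three input
shapes — a negative-binomial single-cell matrix with the CSC-rooted cluster
structure and planted exclusive markers, a branch-dominated bulk cohort with
subtype-dependent exponential survival, and an IHC score table — with full
ground truth, so every stage is testable without external downloads.

## Worked example

```python
import pandas as pd
import ossubtype as ost

cfg = ost.SimulationConfig(seed=1)

# single-cell stage: simulate, QC, normalize, discover marker panels
adata, truth = ost.simulate_single_cell(cfg)
norm = ost.lognormalize(ost.filter_cells_genes(adata))
labels = norm.obs["true_cluster"].to_numpy()
stats = {g: ost.wilcoxon_one_vs_rest(norm, labels, c)
         for g, c in ost.GROUP_TERMINAL_CLUSTER.items()}
panel = ost.select_specific_panel(stats)
print("panel sizes:", panel.sizes)

# bulk stage: consensus subtyping and survival separation
expr, surv, _ = ost.simulate_bulk_cohort(cfg)
result = ost.ConsensusSubtyper(expr, panel, n_resamples=100).fit(seed=1)
print(result.summary())
groups = result.assign_groups()
print(ost.logrank_test(surv.assign(group=surv["sample_id"].map(groups))).summary())
```

prints

```
panel sizes: {'A': 20, 'B': 20, 'C': 20}
Consensus clustering result
  samples: 90   panel genes: 60
  resamples: 100  subsample fraction: 0.8
  k    PAC      cluster sizes
  2    0.6739   [30, 60]
  3    0.0000   [30, 30, 30] *
  4    0.1768   [30, 30, 8, 22]
  5    0.3106   [30, 30, 8, 2, 20]
  6    0.3231   [30, 21, 8, 1, 8, 22]
  chosen k (argmin PAC): 3
Log-rank test: chi2 = 10.5819, df = 2, p = 0.005037
  group    observed  expected
  A        26        27.11
  B        21        11.68
  C        20        28.21
```

All 20 planted markers per branch are recovered into disjoint panels, PAC is
minimized exactly at the three planted subtypes (perfectly stable, PAC = 0),
each consensus group matches one planted group of 30 samples, and the
log-rank test detects the elevated hazard planted in Group B (21 deaths
observed vs 11.7 expected).

A command-line interface mirrors the library:

```bash
ossubtype simulate bulk --seed 1 --outdir data/
ossubtype subtype --bulk data/bulk_expression.csv --panel panel.json \
    --k 2..6 --resamples 500 --seed 1 --outdir out/
ossubtype survive compare --surv data/survival.csv --groups out/labels.csv --outdir out/
```

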