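# Methods

## The classification procedure

The pipeline formalizes a subtyping scheme in which bulk osteosarcoma samples
are assigned to one of three groups (A/B/C) according to which tumor-cell
differentiation branch dominates them.  Its inputs are (i) a clustered
single-cell expression matrix containing the terminal clusters OS-A2, OS-B2
and OS-C2, (ii) a bulk cohort with survival follow-up, and (iii) optionally a
quantified IHC marker table.  The stages and their contracts:

**QC filter.**  Order is fixed as genes-then-cells in a single pass: a gene
is kept if detected (count > 0) in at least `min_cells_per_gene` (default 3)
input cells; cell metrics are then computed on the gene-filtered matrix and a
cell is kept if its detected-gene count lies in `[min_genes, max_genes]`
(default 200–5 000) and its mitochondrial count fraction is at most
`max_mito_frac` (default 0.20).  The ribosomal-fraction rule is exposed as an
explicit three-mode switch (`off` / `remove_below` / `remove_above` a 5% cut,
default `off`) because the conventional direction of that filter is ambiguous
in practice; we decline to hard-code a guess.  Emptied outputs raise an error
carrying the per-rule removal counts.

**Normalization** is `ln(1 + c/total × 10⁴)` per cell.  Zeros map to zeros,
within-cell rank order is preserved, and a zero-total cell is an error naming
the cell rather than a silent NaN.

**Variable genes** are ranked by the "vst" convention: per-gene values are
standardized by the expected standard deviation from a mean–variance trend,
clipped above at √n_cells, and the variance of the clipped values is the
ranking statistic; ties break lexicographically by gene id.  The trend is a
quadratic fit of log₁₀ variance on log₁₀ mean — a parametric stand-in for the
usual loess smoother that behaves equivalently on the smooth mean–variance
relations produced here.  Constant genes score 0.

**Clustering** is PCA (on per-gene z-scored values of the selected genes)
followed by k-means with 10 restarts and a fixed seed.  The downstream
classification needs cluster *labels*, not any particular community-detection
algorithm; PCA + k-means keeps the contract testable (label recovery against
simulation truth via the adjusted Rand index) with no graph dependency.
Batch correction and doublet removal are out of scope: the synthetic data
contain neither batches nor doublets.

**Marker statistics.**  For a cluster vs the rest, each gene gets a two-sided
Wilcoxon rank-sum p (exact enumeration when both sides have ≤ 10 untied
values, otherwise the normal approximation with tie and continuity
corrections), a BH-adjusted q across genes, detection fractions in/out, and
the effect `ln((mean_in + 1)/(mean_out + 1))` where the means are of
`expm1`-restored normalized values — the natural-log fold change with a
pseudocount of 1.  A pairwise (cluster-vs-cluster) mode is provided.

**Panel selection** operationalizes "most specific markers": per terminal
cluster, candidates satisfy `q ≤ 0.05`, `effect ≥ ln 1.5`, `pct_in ≥ 0.25`
and `pct_out ≤ 0.25`; any gene qualifying for two or more clusters is removed
from *all* panels; survivors are ordered by effect (ties by gene id).  The
exclusivity rule is what reproduces the near-disjointness of per-branch
marker sets; panel sizes are free to differ across groups.  Thresholds are
recorded in the panel's provenance and the selection errors out (rather than
returning an empty panel) when nothing survives.

**Consensus subtyping** follows the standard resampling protocol: per-gene
z-scoring across the cohort (otherwise high-abundance FPKM genes dominate
Euclidean distances), 500 resamples (100 in the test suite) each drawing 80%
of samples without replacement, k-means (10 restarts) at each candidate
k ∈ {2..6}, and consensus `M_ij` = co-clustered count / co-drawn count.
Final labels at each k cut an average-linkage dendrogram of `1 − M`; k is
chosen by minimum PAC, the off-diagonal consensus mass between 0.1 and 0.9.
Pairs never co-drawn are flagged and set to 0 with a warning.  The resample
plan (index sets and inner seeds) is derived deterministically from the seed
and exposed (`make_resample_plan`) so a replay oracle can reproduce the
matrix exactly.  Clusters are named A/B/C by the argmax of their mean
within-cluster panel z-score; two clusters claiming one group is an error,
not a silent merge.

**Single-sample classification.**  `panel_mean` averages a group's panel
genes after cohort normalization; `single_marker` takes the maximum
normalized marker per group — the IHC "strongest expressed marker" rule.
Because raw marker intensities are not cross-comparable, markers are
standardized across the cohort before the argmax (z-score default, rank
available).  Ties are resolved alphabetically and always flagged; the margin
(top minus runner-up score) is reported per sample.

**Survival.**  Kaplan–Meier and the g-sample log-rank test are implemented
from first principles (they are part of the artifact's contract, with
lifelines used only as an independent oracle in the tests).  Tie convention:
subjects censored at an event time remain at risk at that time.  The
log-rank χ² uses the pseudo-inverse of the (g−1)-dimensional hypergeometric
covariance, so degenerate tables (identical groups) yield χ² = 0, p = 1
rather than a division error.  Dichotomization splits samples at the median
panel-mean score (default) or into upper-vs-lower tertiles with the middle
third dropped; a constant score vector is a documented error.

## The synthetic-data model

The generator encodes exactly the three assumptions the analysis needs —
exclusive branch markers, branch-dominated bulk samples, subtype-dependent
hazard — in the simplest standard forms:

* **Single cell:** counts are negative binomial with
  `Var = μ + φμ²` (dispersion φ = 0.3).  Gene baselines are log-normal
  (mean 0.5, log-sd 0.3); each of the 10 clusters (CSC root, six branch
  clusters, three normal populations of 200 cells each) multiplies its own
  20 planted markers by `exp(1.5)`; marker sets are disjoint by construction.
  Expected per-cell totals are uniform on 900–1 100 counts over 2 000 genes.
  Planted markers are drawn with a lower baseline (0.45× background, log-sd
  0.1): lineage-restricted genes are sparsely detected outside their lineage,
  which is both how real markers behave and the regime the
  detection-fraction screen (`pct_out ≤ 0.25`) assumes.  At these settings
  markers are detected in ~20% of cells outside and ~55–60% inside their
  cluster, background genes near 35–40%, and cells detect ~700 genes —
  droplet-style sparsity scaled to the reduced 2 000-gene universe (QC
  defaults therefore pass unchanged).
* **Bulk:** each sample is `purity × (terminal-cluster mean profile) +
  (1 − purity) × (mean profile of the three normal clusters)` plus
  N(0, 0.2) noise, clipped at 0; default 30 samples per group at purity 0.7.
  Profiles are the generator's analytic NB means at the midpoint library
  size, so the noise-free limit is exact.
* **Survival:** exponential with per-group hazards (default A = C = 0.1,
  B = 0.2 — the B-like subtype carries the worst outcome); independent
  exponential censoring with its rate chosen so the expected censored
  fraction equals `censoring_rate` (default 0.25).
* **IHC:** markers of a sample's true group score `base + effect + noise`
  (1 + 2 + N(0, 0.5)), others `base + noise`, clipped at 0.

All randomness flows from one root seed through fixed per-stage streams
(gene model / single-cell / bulk / IHC), so any stage can be re-run
independently and identical configs are bitwise reproducible.

What the generator does **not** emulate: pseudotime gradients within
branches, batch effects, doublets, ambient RNA, copy-number structure,
gene–gene correlation beyond the cluster means, or non-proportional hazards.
Passing tests therefore demonstrate that the pipeline recovers the planted
structure under its own assumptions — not that those assumptions hold in any
real cohort, where panel sizes and subtype boundaries will differ.

## Numerical and design choices

* Fold-change effects use a pseudocount of 1 inside the log ratio, so
  all-zero genes give effect 0 rather than −∞.
* A gene constant across all cells has zero rank variance; its p is defined
  as 1 (no evidence) instead of NaN.
* PAC ties across k resolve to the smaller k; k = 1 anywhere in the pipeline
  is accepted but flagged (single cluster, naming skipped).
* The k-means inner clusterer seeds derive from the resample plan, making
  the consensus matrix a pure function of (data, protocol, seed).
* Assignment ties are exact-equality by default (`tie_tol = 0`); the tie is
  broken alphabetically and always flagged rather than hidden.
* The high/low survival split for a panel uses the median by convention; the
  tertile cut is the appropriate design when the high-risk subtype is an
  expected one-third of the cohort, since a median split necessarily dilutes
  the high group with low-risk samples (the replicate-power check in the
  test suite uses tertiles for exactly this reason).
* Study sizes in the test suite and acceptance script: 2 000 cells × 2 000
  genes for the single-cell stage, 90-sample cohorts, 100 consensus
  resamples, and 200-replicate calibration loops — small enough to run
  anywhere, large enough that every planted effect is comfortably inside its
  detection margin.

## Known limitations

* Panel sizes on real cohorts are not promised: the selection thresholds
  that produced the published 24/9/11 split are not recoverable, only the
  selection *rule* (threshold pass + exclusivity + effect ranking) is.
* The normal-approximation rank-sum p is mildly approximate for heavily tied
  sparse genes; the exact path covers only small group sizes.
* Consensus clustering cost grows as resamples × |k_range| k-means runs;
  cohorts of thousands of samples would need a smaller inner restart count.
* The survival module intentionally stops at KM/log-rank — no Cox models or
  hazard-ratio confidence intervals.
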