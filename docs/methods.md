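# Methods

`histocomp` implements a complete in-silico version of a multi-platform
workflow for dissecting lung adenocarcinoma (LUAD) histological
heterogeneity: region-level spatial transcriptomics defines lepidic and
acinar signature gene sets, single-cell RNA-seq applies them to individual
tumour cells, and the signatures are evaluated as prognostic risk scores.
Every stage runs on synthetic data with planted ground truth, so the whole
chain is testable end to end.

## Study design emulated by the generator

One `SimConfig` drives four generators that share planted truths through the
seed:

* **scRNA-seq** (`simulate_scrna`): paired tumour/normal samples per patient.
  Counts are gamma–Poisson (negative binomial, `Var = mu + phi mu^2`,
  `phi = nb_dispersion = 0.4`) with gene base means log-normal
  (median 2 counts/cell, sigma 1), a per-cell log-normal library factor
  (sigma 0.3), a scalar per-patient offset (sigma 0.15) and independent
  Bernoulli dropout (rate 0.1) applied after sampling. Ten cell types are
  planted through the marker panel; lineage markers are modelled as
  near-binary (base median 0.02 counts, `2**10` in the owning type), which
  is what makes the mean-z marker score a workable classifier — markers
  expressed at an appreciable baseline in every type would cap the
  achievable z-separation for prevalent types such as epithelium.
  Tumour cells are epithelial, carry the subtype signature shift
  `2**planted_log2fc` (default `log2FC = 1.5`, i.e. fold change 2.83,
  comfortably past the downstream discovery cut of 1.5), and a copy-number
  gain `2**cnv_gain_log2` on a contiguous 200-gene segment of chr1.
  Mitochondrial contamination is planted through 13 reserved `MT-` genes at
  a per-cell fraction uniform on [0.02, 0.12], so the 10% QC rule actually
  removes cells.
* **DSP-like AOIs** (`simulate_dsp`): two ROIs per region
  (normal/lepidic/acinar), each split into PanCK+/CD31+/CD45+ compartments
  (18 AOIs). AOIs are deep aggregate measurements: gene dispersion 5e-4,
  base medians ~5e4 counts, three IgG isotype controls at mean 5e3, and a
  per-AOI collection-efficiency factor (sigma 0.3) multiplying every
  feature — the nuisance that IgG normalization exists to remove. Region
  signatures are planted in PanCK+ AOIs only.
* **Visium-like spots** (`simulate_visium`): 100 spots per region, spot
  dispersion 0.3, ~2.5e4 counts/spot across the 800-gene panel.
* **Survival cohorts** (`simulate_survival_cohort`): exponential baseline
  hazard with proportional hazards `exp(x·beta)`, independent exponential
  censoring, and age/sex/smoking covariates.

### Why these sizes and noise levels

The defaults were fixed by a power analysis of the pipeline's own discovery
rule, not tuned to individual test runs:

* With two AOIs per group, a two-sample t-test has 2 degrees of freedom and
  heavy tails (`p ≈ 1/t²`), so clearing a Benjamini–Hochberg cut of
  ~0.004 over 800 genes needs per-gene `|t| ≳ 17`, i.e. per-AOI log2 noise
  below ~0.04 at the planted effect. That corresponds to AOI aggregates of
  millions of reads — the regime the DSP parameters encode.
* The 800-gene panel is a miniature transcriptome. The copy-number segment
  (200 genes) plus its 51-gene smoothing halo must cover well under half of
  all window positions for the per-cell median to sit on diploid baseline;
  three 250-gene autosomes (plus chrM) satisfy this with the halo at ~32%.
* Default compositions give exactly 500 tumour cells per patient
  (1250 cells × 0.5 tumour-tissue fraction × 0.8 purity) across 8 patients,
  with acinar-predominant mixtures typical of resected early-stage LUAD.

## Pipeline stages

**QC and annotation.** Cells need ≥200 detected genes and a mitochondrial
fraction not above 10% (strictly-greater values are discarded); genes must
be detected in more than 3 of the surviving cells, computed after the cell
filter. Normalization is counts-per-10k + `log1p`. Cell types are scored as
the mean z-score (across cells) of each type's present markers and assigned
by argmax with a lexicographic tie-break. An optional per-batch gene-median
centering stands in for heavier batch integration.

**CNV tumour calling.** Per-gene log2 ratios of linear normalized
expression against the mean of normal epithelial reference cells
(pseudocount 1), centered so reference cells average zero, a centered
51-gene moving average within each chromosome (chrM excluded — its windows
track contamination, not dosage), per-cell median centering (a gain covering
a large genome fraction inflates the library total and depresses every
other window; the median restores the diploid baseline), and clipping at
±3. The burden statistic is the mean squared window value; a cell is called
tumour when its burden exceeds the reference mean by `k = 2` reference
standard deviations. The burden threshold and window are deliberately
simple: the goal is a tumour/normal selection, not segmentation or clonal
structure.

**Spatial differential expression.** DSP AOIs are divided by surface area
and then by the per-AOI geometric mean of the (area-scaled) IgG controls;
Visium spots get library-size + `log1p` normalization. Differential
expression is a two-sided pooled-variance Student t-test on `log2(x+1)`
values. Pooling, rather than Welch, is a deliberate choice: at the design
size of two AOIs per group Welch's Satterthwaite df collapses toward 1
(each group's variance estimate has a single degree of freedom), flooring
the attainable p-value near 0.02 regardless of effect size, which would
make the discovery rule unattainable; the pooled test keeps its nominal
`n1+n2-2` df. Fold change is the ratio of linear group means with
pseudocount 1. Discoveries require fold change strictly > 1.5 and BH FDR
strictly < .05.

**Signature derivation.** Per platform, subtype-specific up-lists are the
set difference (up in this subtype vs normal, not up in the other subtype);
the final signature per subtype is the DSP∩Visium intersection, ordered by
descending DSP log2 fold change, with per-platform provenance flags. The
two final sets are disjoint by construction. Generic enrichment utilities —
one-sided hypergeometric over-representation with BH across the collection,
and a preranked weighted-KS enrichment score (weight exponent 1) with a
two-sided gene-set-permutation p — cover downstream annotation needs
without any ontology handling.

**Subtype scoring.** The module score of a signature in a cell is the mean
log-normalized expression of its genes minus the mean of `n_ctrl = 50`
control genes drawn, per signature gene, from the same average-expression
bin (`n_bins = 25` equal-frequency bins; draws seeded). Because bins are
formed on population averages, cells lacking the programme score below
zero, which yields a parameter-free three-way rule: argmax of the two
scores when positive, "other" otherwise (ties included). Per-patient
compositions are class frequencies over tumour cells; patients with no
classified cells are reported missing rather than zero. Concordance with
the bundled 11-patient clinicopathology table reports per-patient absolute
differences and the across-patient Spearman rank correlation of the lepidic
fraction (micropapillary and complex-glandular percentages fold into
"other").

**Survival.** The Cox model maximizes the Breslow partial likelihood by
Newton–Raphson with step halving, tolerance 1e-8 on the score norm, at most
50 iterations; ties share their risk-set denominator (the generator's
continuous times make ties measure-zero anyway). Monotone likelihood is
reported as separation both when a coefficient diverges past 30 during
iteration and when a "converged" coefficient exceeds 15 — the gradient also
vanishes as beta → ∞, so convergence alone does not certify a maximum.
Confounders (age/sex/smoking) are screened univariately and retained at
Wald p < .05. Each signature gets its own multivariate fit; the patient's
risk score is the plain linear predictor over signature genes. Both scores
are dichotomized strictly above their cohort mean; the discordant cells
(lepidic-high & acinar-low vs acinar-high & lepidic-low) are compared by
Kaplan–Meier and the standard log-rank test (via lifelines). For n ≤ 9
paired observations with no ties, the Spearman p-value enumerates all n!
rank permutations and counts `|rho| ≥ |rho_observed|` two-sidedly;
otherwise the t-approximation is used and flagged.

## What the synthetic data does and does not show

The generator reproduces the moments that the pipeline's statistics consume
(overdispersed counts, sparsity, library and batch scaling, compartment
identity, planted effect sizes) but not spatial autocorrelation, ambient
RNA, doublets, cell-cycle structure, subclonal CNV heterogeneity, or
platform-specific probe biases. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under a faithful noise
model, not their field performance on tissue data. In particular, planted
signatures are exactly disjoint and exactly multiplicative — real
signature recovery will be bounded by biology, not only by the statistics
checked here.

## Numerical conventions

Pseudocounts: 1 throughout (CNV ratios, DEG fold changes, DEG log
transform). Degenerate t-tests (identical zero-variance groups) are defined
as t = 0, p = 1. Empty cross-platform intersections are valid results with
a warning. Exact ties: cell-type argmax breaks lexicographically; equal
positive module scores classify as "other"; risk-score "high" means
strictly greater than the mean. All stochastic steps (generators, control
sampling, permutation nulls) accept explicit seeds and are reproducible
byte-for-byte.

## Problem sizes used in the shipped checks

The default study (8 patients × 1250 cells, 800 genes, 18 AOIs, 300 spots)
runs the full single-cell arm in a few seconds on one core; the null-FDR
calibration uses 200 DSP replicates and the log-rank calibration 500
cohorts of 100, sizes at which the Monte-Carlo standard errors are well
below the margins being asserted.
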