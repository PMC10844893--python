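# histocomp

Histological growth patterns of lung adenocarcinoma (LUAD) — non-invasive
**lepidic** versus invasive **acinar** — carry strong prognostic information,
but their per-patient percentages are estimated visually by pathologists.
`histocomp` implements a reproducible computational pipeline for this
problem, aimed at computational biologists working with spatial and
single-cell transcriptomics:

1. **Signature derivation** — differential expression in pathologist-drawn
   regions on two spatial platforms (GeoMx-DSP-like areas of illumination
   and Visium-like spots), with the discovery rule *fold change > 1.5 and
   BH FDR < .05*, subtype-specific set differences, and a cross-platform
   intersection yielding disjoint lepidic/acinar signature gene sets.
2. **Single-cell composition** — scRNA-seq QC (≥200 detected genes,
   mitochondrial fraction ≤ 10%, genes in > 3 cells), marker-panel cell-type
   annotation, moving-average copy-number inference to select tumour cells
   (burden above the normal-epithelial reference by *k* = 2 SD), control-bin
   module scores per signature, and a three-way lepidic/acinar/other call per
   tumour cell giving per-patient composition estimates that can be compared
   with pathologist percentages.
3. **Survival association** — confounder screening, multivariate Cox fits
   per signature (Breslow partial likelihood, Newton–Raphson), the linear
   risk score `sum_i expr_i × Coef_i` dichotomized at the cohort mean,
   Kaplan–Meier + log-rank on the discordant risk groups, and an exact
   permutation Spearman test for small-n compartment correlations
   (all *n*! rank permutations enumerated for *n* ≤ 9).

Because the motivating tissue data are access-controlled, the package ships
a first-class synthetic-data module (`histocomp.simulate`) that plants
ground-truth signatures, copy-number gains, cell types, per-patient subtype
compositions and proportional-hazards survival — every stage is therefore
testable end to end. See `docs/methods.md` for the model details and design
choices.

## Worked example

```python
import histocomp as hc

cfg = hc.SimConfig(seed=1)                       # default study conditions
res = hc.derive_signatures(cfg)                  # DSP + Visium -> signatures
comp = hc.recover_compositions(cfg, signatures=res["signatures"])
r = hc.spearman_exact([1, 2, 3, 4, 5, 6], [5, 6, 4, 3, 1, 2])
```

This prints (seed 1):

```
lepidic: 39 signature genes   acinar: 40 signature genes

per-patient compositions (predicted vs planted):
  P01: predicted {'lepidic': 0.5, 'acinar': 0.32, 'other': 0.18} | planted {'lepidic': 0.51, 'acinar': 0.3, 'other': 0.19}
  P02: predicted {'lepidic': 0.21, 'acinar': 0.58, 'other': 0.21} | planted {'lepidic': 0.22, 'acinar': 0.57, 'other': 0.21}
  P03: predicted {'lepidic': 0.73, 'acinar': 0.19, 'other': 0.08} | planted {'lepidic': 0.7, 'acinar': 0.21, 'other': 0.09}
per-class MAE: {'lepidic': 0.015, 'acinar': 0.013, 'other': 0.017}

Spearman rho = -0.886, exact two-sided p = 0.033 (exact, n=6)
```

The derived signatures recover the planted gene sets (39–40 of 40 per
subtype at seed 1) and the per-patient subtype proportions are recovered
with a mean absolute error under 0.02 per class. The last line is the exact
small-n Spearman machinery on the six-region CD8/PD-L1 rank pattern: a
strong negative correlation whose two-sided permutation p-value counts the
24 of 720 rank permutations at least as extreme.

A thin CLI mirrors the library (`histocomp simulate/qc/annotate/cnv/deg/
signatures/score/survive/correlate`); run `histocomp --help`.

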