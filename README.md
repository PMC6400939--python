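# hs27pipe

Quantitative analysis pipeline for fluorescence imaging of breast-biopsy
specimens stained with a fluorophore-tethered Hsp90 inhibitor (HS-27).
Surface ("ectopic") Hsp90 is selectively expressed by breast cancer cells, so
a topically applied, fluorescently labelled Hsp90 ligand lights tumor tissue
up more brightly than benign lesions, and benign lesions more brightly than
normal (reduction-mammoplasty) breast tissue. The package turns stacks of
per-site microendoscope frames into a biopsy-level diagnosis and the
supporting statistics, and ships a seeded synthetic-cohort generator so the
whole pipeline is testable end to end without clinical images.

## What it computes

**Specificity-ratio optimisation** (pre-clinical arm design): each
specific-probe (HS-27) image is divided by the arm-wise mean fluorescence of
a non-binding control analog (HS-217), giving per-pixel specificity ratios
r = I_HS27 / mean(I_HS217). Per arm the pipeline builds survival curves
S(t) = 1 − F(t) of the ratios on a shared grid, averages them (mean ± SEM
over biopsies), compares arms with two-sample Kolmogorov–Smirnov tests, and
ranks arms by mean ratio.

**Feature extraction**: per biopsy, frames are calibrated
(I → I / (slide_mean · gain/gain_ref · exposure/exposure_ref)), stitched
side-by-side, and the masked pixels pooled. From the pooled pixels and from
their brightest 1%, the empirical CDF is fitted with a three-parameter
logistic

    F(x) = C / (1 + exp(−A·(x − B)))

(A: slope ≈ inverse spread, B: horizontal shift ≈ mean, C: upper asymptote ≈
bright-tail mass), and the sample mean, variance and max/min ratio are
added — 12 optical predictors per biopsy.

**Classification**: Gaussian-kernel (RBF) soft-margin SVMs for
tumor-vs-mammoplasty and tumor-vs-benign, with exhaustive selection over all
12 single features and all 66 pairs by cross-validated AUC (stratified
k-fold, out-of-fold decision scores), ROC construction, and the operating
point that maximises Youden's J = sensitivity + specificity − 1.

**Cohort statistics**: Pearson correlations of mean fluorescence with tumor
cellularity and with TIL density (TIL% of stroma / stromal %), receptor
subtype and tissue-class comparisons via Welch t-tests and one-way ANOVA
with Tukey–Kramer post-hoc testing.

## Worked example

```python
from hs27pipe import GeneratorConfig, generate_cohort, compute_features_table, run_task

cohort = generate_cohort(GeneratorConfig(), seed=1)   # 27 tumor / 10 benign / 6 mammoplasty
table = compute_features_table(cohort)                # 43 rows x 12 predictors
report = run_task(table, "tumor_vs_benign", k=10, seed=1)
print(report.selection.best_set, round(report.roc.auc, 3))
print(round(report.operating_point.sensitivity, 2),
      round(report.operating_point.specificity, 2))
```

On this synthetic cohort the selected pair and operating point come out as

```
('cdf_B_all', 'var_all') 0.922
0.85 1.0
```

i.e. the best tumor-vs-benign classifier pairs the CDF horizontal-shift
parameter of all pixels with the all-pixel variance, reaching a
cross-validated AUC of 0.92 with 85% sensitivity at 100% specificity at the
Youden-optimal threshold. The easier tumor-vs-mammoplasty task saturates
(AUC 1.0 on this cohort), mirroring the much larger intensity and
homogeneity gap between tumors and normal reduction tissue.

The same objects drive the CLI:

```bash
hs27 run-all --out run1 --seed 1          # simulate -> features -> classify -> stats -> optimize
hs27 classify --out run1 --task tumor_vs_benign --seed 1
```

`run-all` writes `features.csv`, per-task `report_*.json`/`roc_*.csv`,
`stats_report.json`, `arm_curves.csv`/`ks_table.csv` and a `manifest.json`
with SHA-256 hashes of every output (re-running with the same config and
seed reproduces the hashes exactly).

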