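# Methods

## Imaging model and calibration

A biopsy is imaged as an ordered series of frames, one per millimetre of
tissue, through a fiber-bundle microendoscope with a circular field of view.
The camera runs automatic gain and exposure and the system's absolute
sensitivity drifts day to day, so raw intensities are comparable only after
normalisation. The calibration model is linear:

    I_cal = I_raw / (slide_mean · (gain / gain_ref) · (exposure / exposure_ref))

where `slide_mean` is the mean intensity of a fluorescence reference slide
imaged in the same session. No published formula exists for this correction;
division by the slide mean and by the gain/exposure ratio is the minimal
model that makes sessions comparable, and because it is linear the order of
calibration and stitching is irrelevant — the pipeline calibrates per frame
before stitching, for reproducibility.

Stitching is masked side-by-side concatenation in site order. All downstream
analysis consumes the pooled pixel *distribution*, which is invariant to
frame placement, so no registration, overlap blending, flat-fielding or
fiber-pattern removal is attempted.

## Pixel-distribution features

Biopsy images routinely contain non-lesion tissue, so features are taken
from the intensity distribution rather than from spatial structure. Per
biopsy the pipeline computes the empirical CDF of the pooled masked pixels
and of their brightest 1% (`ceil(0.01·n)` pixels, ties included up to the
count). CDFs are evaluated on a fixed 1000-point grid over max-normalised
intensity ([0, 1]); a shared abscissa is required because curves are
averaged across biopsies within groups and because the logistic parameters
must be comparable across biopsies whose absolute ranges differ. Whether to
fit raw or rescaled intensities is an open choice; normalised-grid fitting
is this package's documented one.

Each CDF is fitted by nonlinear least squares with the three-parameter
logistic F(x) = C / (1 + exp(−A(x − B))) — the only three-parameter logistic
in which A is a pure slope, B a pure horizontal shift and C a pure vertical
scaling of the top. Initialisation: A₀ = 2.2 / interquartile rise (a
logistic climbs from 0.25C to 0.75C over ≈ 2.197/A), B₀ at the median, C₀ at
the final cumulative probability. Bounds keep A positive and C in (0, 1.05]
(small overshoot tolerated and flagged). A degenerate CDF with all mass at
one grid step cannot constrain the slope: the fit is returned non-converged
with A capped at 10⁶, B at the step location, and C = 1. Noisy sampled
curves are not monotone, so the fitter also accepts a raw `(grid, probs)`
pair; the monotonised curve is used only for initialisation quantiles.

The six summary features are the sample mean, sample variance (n − 1
denominator; the convention is irrelevant to classifier ranking at these
n), and the max/min dynamic-range ratio for each pixel bin. Near-zero dark
pixels would blow the ratio up, so the denominator is floored at the
smallest positive value in the sample (configurable ε).

## Specificity-ratio analysis

The unit of the pre-clinical optimisation is the per-pixel ratio of
specific-probe intensity to the arm-pooled (pixel-weighted) mean of the
non-binding control. Per arm, per-biopsy survival curves 1 − F(t) are
evaluated on one shared ratio grid (1000 points spanning all arms) and
averaged with a pointwise SEM (sd/√n over biopsies). Arms are compared with
two-sample KS tests on the pooled per-arm ratio samples. Millions of pixels
make any difference "significant", so each arm is subsampled without
replacement to a configurable cap (default 2000 pixels, seeded) before
testing; `cap=None` tests the full pools, and the per-biopsy-curve unit
remains available through the stored curves. Arms are ranked by mean
specificity ratio with KS significance annotations.

## Classification

Both diagnostic tasks (tumor vs. mammoplasty for margin-style assessment,
tumor vs. benign for biopsy triage) use a soft-margin SVM with a Gaussian
kernel; tumor is the positive class and scores are oriented so higher means
more tumor-like. The box constraint defaults to C = 1 and the kernel
bandwidth to the median-pairwise-distance heuristic, γ = 1/(2m²) with m the
median Euclidean distance between standardised training rows — standard,
fully reproducible defaults, both overridable. Features are z-scored with
training-fold statistics only; the no-leakage property is asserted in tests
by perturbing held-out biopsies.

Feature selection is exhaustive over all single features and all pairs
(n + n(n−1)/2 = 78 candidate sets for 12 features), scored by the AUC of
pooled out-of-fold decision values from seeded stratified k-fold CV. Ties
favour fewer features, then lexicographic feature order. Ten-fold CV is
impossible when a class has fewer than 10 members (the default cohort has 6
mammoplasty biopsies); the fold count is reduced to the minority class size
with a logged warning. The ROC is swept over the unique pooled scores with
`score ≥ threshold ⇒ positive`; the trapezoidal AUC then equals the
tie-adjusted pairwise concordance probability, which the tests verify
against a brute-force oracle. The operating point maximises Youden's
J = sens + spec − 1, with ties broken toward higher specificity (the
conservative choice for a rule-in cancer diagnostic) and then toward the
higher threshold.

## Cohort statistics

TIL density is TIL%-of-stroma divided by stromal % (stromal % = 100 − tumor
cellularity); the biopsy-level value is the mean over annotated sites, since
the aggregation rule from site-level pathology to one point per biopsy is
otherwise unspecified. Correlations are Pearson's r with two-sided t-based
p-values. Two-group contrasts default to the Welch (unequal-variance)
t-test, with the pooled-variance form available; multi-group contrasts use
one-way ANOVA with Tukey–Kramer honest-significant-difference pairwise
comparisons, valid for unequal group sizes. Significance is α = 0.05
throughout; p-values are reported at machine precision.

## Synthetic cohort generator

No image archive exists for this assay, so the generator emulates the
cohort structure the pipeline targets:

* tissue-class intensity ordering tumor > benign > mammoplasty;
* receptor-subtype ordering Her2+ > TNBC > ER+ among tumors;
* mean fluorescence decreasing with TIL density (pooled r ≈ −0.4 to −0.6
  across the 27-tumor cohort, ≈ −0.6 within the pooled Her2+/TNBC subset),
  with tumor cellularity left uncoupled from intensity;
* much smoother mammoplasty images (heterogeneity amplitude 0.08 of the
  mean vs 0.35 for tumors), reflecting their near-uniform adipocyte content;
* a non-binding control agent for specificity-ratio experiments, with the
  specific probe at a configurable multiple of the control mean.

A site frame is `mean · (1 + amp·G) + ε`, with G a unit-variance Gaussian
random field (white noise smoothed at a 20-pixel correlation length), ε
i.i.d. N(0, noise_sd = 8), clipped at zero, under a circular inscribed
mask. The site mean is `baseline + subtype_offset + til_slope · density +
biopsy_shift`. Defaults (arbitrary units — the instrument's dynamic range
is unstandardised): baselines 160/90/55 (tumor/benign/mammoplasty) with
between-biopsy SDs 6/10/8; subtype offsets −25/+80/+25 (ER+/Her2+/TNBC);
til_slope −130 per unit density. Frames are 256×256 with 5 frames per
biopsy — large enough for stable distribution features, small enough for
fast full-cohort runs.

Pathology annotations are drawn at the *biopsy* level (uniform centers:
tumor cellularity 20–60%, TIL 0–35% of stroma, tumor area 20–90%) with
Gaussian site-level jitter (SDs 5/3/10), because infiltration and
cellularity are biopsy-level biology with modest site-to-site variation;
drawing sites independently would shrink between-biopsy TIL variance by
√n_sites and erase the cohort-level correlation the generator is meant to
carry. Benign and mammoplasty sites have no tumor area and only sparse
lymphocytes (TIL 0–10% and 0–5%), so their realised group means sit a few
units below their baselines. Default parameter magnitudes were chosen (and
verified by Monte-Carlo at the biopsy-mean level) so each ordering holds
reliably in a single 27/10/6 cohort, not just asymptotically.

Randomness is hierarchical (cohort → biopsy → frame) from one seed via
`numpy` SeedSequence spawning, so cohorts are bit-reproducible and adding a
biopsy never perturbs earlier ones. Tumor subtypes are apportioned
deterministically by largest remainder from the configured proportions
(18/27 ER+, 5/27 Her2+, 4/27 TNBC — the clinical cohort composition), so the
default 27-tumor cohort splits exactly 18/5/4.

What passing tests on synthetic cohorts do **not** show: the generator has
no optical physics (PSF, photobleaching, fiber-bundle artifacts), no spatial
lesion structure within frames beyond the smooth heterogeneity field, no
class-conditional feature correlations beyond those induced by the mean
model, and arbitrary intensity units. Classifier AUCs near 1 on synthetic
data therefore demonstrate pipeline correctness, not expected clinical
performance.

## Problem sizes and numerical choices

Default analyses use 1000-point CDF/survival grids, 10-fold (auto-reduced)
CV, a 2000-pixel KS subsampling cap, and the 27/10/6 cohort at 256×256×5
frames; tests exercise the same code paths at reduced frame sizes where the
full size adds nothing. Each end-to-end cohort run (generation, features,
both classifiers with 78-set selection, statistics) takes a few seconds on
one CPU. Floating-point ties in feature selection and the Youden scan are
broken by the documented deterministic rules; the exponential in the
logistic is clipped at ±500 in the argument to avoid overflow at the capped
slope.

## Known limitations

* The calibration formula, logistic CDF form, KS sample unit and CV fold
  handling for the 6-member class are all choices this package documents
  rather than published prescriptions; alternatives (e.g. per-biopsy-curve
  KS testing, raw-intensity CDF fitting) are configurable or noted.
* Clinical performance numbers reported for this assay were computed on
  patient images that are not publicly deposited; nothing in this package
  reproduces them, and the synthetic cohort is not a substitute for
  clinical validation.
* The max/min dynamic-range feature is heavily influenced by the darkest
  retained pixel and the ε floor; it is kept for completeness of the
  12-predictor set but is the least stable feature.
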