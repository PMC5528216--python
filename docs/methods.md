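# Methods

## The measurement problem

Blubber is loose connective tissue: lipid-filled adipocytes embedded in a
matrix of collagen, vessels and other cells (the *intervacuolar* space).
Because adipocyte number is essentially fixed in adult mammals, changes in
stored energy show up as changes in adipocyte size. Two image-derived
measures of a stained blubber section are implemented here:

* **Adipocyte area** — per-cell cross-sectional area under a circular
  model. A connected component of `k` adipocyte pixels at calibration `s`
  µm/px is assigned the equivalent-circle diameter
  `d = 2·sqrt(k·s²/π)` and the area `π(d/2)²` (identically `k·s²`; the
  diameter is carried so a caliper/Feret estimator can be substituted).
  Border-touching components are excluded; a per-sample mean requires at
  least `min_cells = 100` complete cells, otherwise the pipeline raises
  rather than silently reporting a noisy mean.
* **Adipocyte index (AI)** — a whole-image ratio from a single intensity
  threshold. With adipocyte pixel fraction `a`, the default definition is
  `AI = 1/a` (total area over adipocyte area, lower bound exactly 1); the
  strict matrix-to-adipocyte ratio `(1−a)/a` is available by
  configuration, and the two differ by exactly 1 for every mask. The
  default was chosen because observed AI values in this kind of study are
  bounded below by exactly 1, which only the total-over-adipocyte reading
  produces. Every AI records the definition, threshold and image area
  that produced it. A valid AI requires an image of at least
  167,687.3336 µm² (a representative field at 10× magnification); smaller
  images raise unless forced.

## Intensity convention and thresholding

Image files store light-is-high intensities (0 = black). The histology
protocol this package follows states intensities dark-is-high (0 = white,
255/65,535 = black) so that a *high* threshold captures the darkly
stained matrix. Images are converted internally to the dark-is-high
scale, and a pixel is classed intervacuolar when its dark-scale value is
at or above the threshold. The default thresholds are 65,527 for 16-bit
and 255 for 8-bit images (the 8-bit value is the proportional rescaling
65,527/65,535 → 254.97, rounded to 255); both the raw and resolved
thresholds are logged in each mask's provenance, and one threshold must
be used across a sample set. These defaults suit heavily stained
material where the matrix is near-black; the operator chooses (and then
freezes) the threshold for their own staining, and the synthetic images
below are segmented at mid-range.

Adipocyte regions are 8-connected (matrix implicitly 4-connected, the
standard duality). Components below `speck_floor_px = 20` pixels are
discarded as debris — nuclei and stain specks, which the original manual
workflow removed by hand. Watershed declustering of touching cells
(seeds = distance-transform maxima separated by at least half the median
equivalent diameter) is available but off by default, since clustered
cells were corrected manually in the workflow this replaces. Images
whose adipocyte fraction falls below 0.5 are flagged by the QC gate,
operationalizing the protocol's active selection of adipocyte-dominated
fields. RGB input is collapsed with BT.709 luminance weights
(0.2125, 0.7154, 0.0721), recorded in provenance.

## Synthetic histology

`generate_tissue_image` renders non-overlapping discs (the circular area
model, so truth and measurement share geometry) by random sequential
adsorption: candidate centre/radius pairs are drawn until
`max_attempts = 100,000` consecutive rejections (saturation) or the
requested cell fraction is reached. Radii are drawn lognormal,
`exp(N(log 14, 0.25))` µm by default — the cell scale seen in humpback
outer blubber. Note that sequential packing accepts small cells
preferentially as the field fills, so the *realized* cell-area
distribution is smaller-bodied than the sampling marginal (mean
interior area ≈ 390 µm² at the defaults). Defaults:
1024×1024 px at 0.5 µm/px (262,144 µm², above the AI area minimum;
0.5 µm/px is typical of a ~3 MP camera at 10×), minimum septum
`matrix_gap_um = 1` µm, Gaussian intensity noise of 3% of dynamic range,
0.3 dark specks per 1,000 µm². The ground truth records the rendered
label mask *before* noise, per-cell pixel areas (so pixel conservation
is exact), the intervacuolar fraction and the implied true AI.

Known limitations of the emulation: disc packing saturates near ~0.55–0.6
area coverage, so synthetic true AI sits around 1.6–1.8 — the upper
(leaner) end of what real blubber shows, because real adipocytes deform
into polygons and reach higher packing; the matrix is a uniform dark
phase without collagen texture, vessels or staining gradients; noise is
white. Passing the recovery tests therefore demonstrates correctness of
the measurement chain on geometrically ideal tissue, not robustness to
every histological artefact; the threshold-choice problem of real H&E
material is deliberately out of scope.

`generate_cohort_table` draws the three metrics through a Gaussian
copula: one latent trivariate normal per sample with the target
correlation matrix, pushed through per-cohort marginals (normal, or
10^normal for right-skewed metrics), then truncated to plausible ranges.
Missingness is specified either as per-metric rates or as exact counts
per observed-metric pattern; the latter gives exact control of
listwise-deletion subset sizes. `CohortTableSpec.study_default()`
encodes the emulated field study: 98 early / 105 late samples; area
normal with cohort means 792.10 / 597.65 µm² and SDs 222 / 139
(estimated as range/4 from the published ranges); AI lognormal with
cohort geometric means 1.35 / 1.49 (combined 1.42) and log10-SD 0.065,
floored at 1; lipid percent with equal cohort means 43% (SD 16) — the
published cohorts were not separable by lipid percent; latent
correlations −0.784 (area, AI), 0.388 (area, lipid), −0.468 (AI,
lipid). The missingness patterns — (all three): 37/40,
(area+AI): 5/1, (AI+lipid): 1/61, (AI only): 55/3 per early/late
cohort — reproduce the published per-metric counts (area 42/41, AI
98/105, lipid 38/101) and the listwise subsets n = 77 (all three),
139 (AI+lipid) and 83 (area+AI) exactly. Note one structural
consequence of the copula: because lipid is correlated with AI but has
no cohort effect of its own, lipid can act as a suppressor variable in
joint models, so backward selection does not drop it on every draw.

## Statistics

Screens follow the standard battery: Shapiro–Wilk normality, Levene's
variance-homogeneity test (classical mean-centred; median-centred
optional), the `k = 2.2` IQR outlier fence with linearly interpolated
quartiles (the fence decision near the boundary depends on the quartile
method, hence it is fixed and documented), and VIF = 1/(1−R²) per
predictor. The two-sample comparison is the pooled-variance Student t
(Welch optional); the AI, being right-skewed, is log10-transformed
before the t-test only — the untransformed AI enters the logistic models,
where normality is not required.

Logistic models are fitted by Newton/IRLS maximum likelihood
(statsmodels `Logit`; relative log-likelihood tolerance 1e-8, 100
iterations), with standard errors from the inverse observed information
and Wald 95% intervals `exp(B ± 1.959964·SE)`. Non-convergence and
(quasi-)separation are reported as distinct errors. Backward
likelihood-ratio selection starts from the full model and, at each step,
computes the 1-df deviance-difference p-value for dropping each current
predictor, removing the largest-p predictor when `p ≥ p_out`
(`p_out = 0.10`, the conventional removal threshold of mainstream
stepwise implementations); the same listwise-deleted cases are used at
every step, and the full trace is recorded. Fit quality is summarised by
Nagelkerke's R² (Cox–Snell `1 − exp(2(LL0−LL1)/n)` rescaled by its
maximum `1 − exp(2·LL0/n)`) and the Hosmer–Lemeshow chi-square over 10
ranked-probability bins (ties kept together, zero-variance bins merged
with a warning), df = bins − 2.

The standard battery fits seven models predicting cohort (early = 0,
late = 1): A (area+AI+lipid), B (AI+lipid), C (lipid+area), D (area+AI)
with backward selection, and univariate E (area), F (AI), G (lipid) by
direct entry. Missing data are handled by listwise deletion per model.
The univariate models are fitted on the complete-case subset (records
with all three metrics) rather than their own listwise subsets, so that
their sample size matches the head-to-head multivariate comparison —
this mirrors how such batteries are reported in the field and is
switchable (`univariate_on_complete_cases=False`). Models with fewer
than 10 cases in either class are skipped with a warning.

Derived quantities: geometric mean `exp(mean(log x))`; spherical volume
from a cross-sectional area, `r = sqrt(area/π)`, `V = (4/3)πr³` µm³ at
10⁶ µm³ per nl; percent reduction `100·(early−late)/early`, reported
separately for arithmetic means, geometric means and volumes, never as
a blended "size" figure.

## Numerical and design choices

* Reproducibility: every generator takes a mandatory seed and uses a
  single `numpy.random.default_rng` stream; identical seeds give
  bit-identical images, tables and reports.
* Packing failure (a requested cell fraction that saturation cannot
  reach) raises an error naming the achieved fraction rather than
  silently under-packing.
* The correlation matrix of a table spec must be symmetric PSD with unit
  diagonal; the copula factor uses an eigendecomposition with negative
  eigenvalues clipped at zero, so exactly-singular targets are accepted.
* Degenerate inputs fail loudly: constant vectors (Shapiro, t-test,
  Pearson), empty cohorts (n = 0 rows, no statistics), zero adipocyte
  pixels (undefined AI), fewer than 4 values (IQR screen warns and
  flags nothing).
* Problem sizes in the test suite and acceptance script (384–1024 px
  synthetic images, 200-replicate selection simulations, 100-replicate
  calibration checks) were chosen as the smallest sizes at which the
  statistical assertions have comfortable Monte-Carlo margins.

## What the tests do and do not show

On noise-free synthetic images the AI equals ground truth exactly and
the mean complete-cell area matches the true interior-cell mean to
within rasterization error (tested at 3%); at default noise the AI is
recovered within ±0.05. The logistic machinery is checked against
independent oracles (closed-form 2×2 log odds ratio, brute-force grid
likelihood maximization, simulation-based type-I/power rates). None of
this certifies performance on real H&E material, where threshold choice,
stain variability and sectioning artefacts dominate; the package's
claim is that given a fixed, operator-validated threshold, the
downstream computation is correct and fully reproducible.
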