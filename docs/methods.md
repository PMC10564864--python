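# Methods

This note documents the models and numerical choices behind `glycoquant`:
what the synthetic generators emulate, how the quantification chain is
defined, how the cohort simulator is calibrated, and what the statistical
pipeline assumes. Parameters listed here are the package defaults; all are
configurable.

## 1. Synthetic H-DAB slides

**What is emulated.** A brightfield whole-slide scan of one or more
paraffin sections of endarterectomy plaque, counterstained with hematoxylin
and immunostained with the brown DAB chromogen for glycophorin C. Pixels
are rendered through the Lambert–Beer law in base-10 optical density using
the standard published H-DAB absorbance vectors (as shipped with
scikit-image), so color deconvolution is exactly invertible on clean input.
Per-slide ground truth (tissue mask, stain mask, exact stained fraction) is
stored alongside the image.

**Geometry.** Each section is a randomly wobbled ellipse confined to its
own vertical strip of the canvas (sections are therefore disjoint by
construction). The stained region is the upper level set of a scalar
field, thresholded at exactly `round(target_fraction × tissue pixels)`
pixels, so the realized fraction equals the target to within one pixel.
Two fields give the two observed morphologies: a smoothed Gaussian noise
field (``diffuse``: many mid-sized patches across the section) and a
distance-to-core field plus noise (``hotspot``: few large blobs near a
section core).

**Degradations.** Multiplicative stain-density texture (±8 %), a linear
illumination gradient (±3 %), and additive Gaussian pixel noise
(σ = 4/255) make thresholding non-trivial; there is no emulation of
scanner artifacts, pyramidal formats, pen marks, or decalcification voids.
Default canvas 2048×2048 px at 0.25 μm/px as a desk-scale stand-in for
multi-gigabyte scans; tests use 256–768 px canvases, which exercise the
identical code path at smaller n.

**What passing tests do not show.** Real slides have stain-intensity
variation across batches, folded tissue, out-of-focus regions and
calcification voids; accuracy numbers on the synthetic material are upper
bounds for real scans, and the validation ρ here (≈1.0) should be read as
"the chain is internally correct", not as a field performance claim.

## 2. Quantification chain

1. **Tissue masking** — background glass is near-white and unsaturated;
   tissue is thresholded on the HSV saturation channel by Otsu with an
   absolute floor of 0.04 (so a blank slide yields an empty mask), then
   objects < 500 px are removed and holes < 500 px filled.
2. **Tiling** — row-major grid of half-open boxes [y0,y1)×[x0,x1) in
   0-based pixel coordinates, edge boxes clipped; a tile is kept iff it
   contains ≥ 1 masked pixel. Boxes partition the slide, which makes
   pixel-conservation exactly testable. Default tile size 512 px (minimum
   64).
3. **Per-tile stain counting** — RGB → optical density → H-DAB
   deconvolution; the DAB concentration channel is thresholded at 0.15
   (OD multiples of the unit DAB vector), objects < 30 px are removed as
   speckle, positives are counted inside the tissue mask only.
4. **Aggregation** — pixel counts scale by (μm/px)² to areas;
   `percent_stain = 100 × stained / plaque`. Multiple sections pool into
   one denominator; per-section reporting is deliberately out of scope.

The DAB threshold, object-size minima and tile size are package decisions,
not reconstructions of any particular laboratory pipeline; they are exposed
as `QuantParams` and on the CLI. On noise-free synthetic input the chain
reproduces the truth-mask pixel counts exactly (with the speckle filter
disabled, since truth components clipped at tile borders may legitimately
lose sub-30-px fragments); with default noise the per-slide percent is
accurate to ≲ 5 % relative + 1 point absolute, and varies < 0.5 points
across tile sizes.

## 3. Cohort simulator and its calibration

One row per patient, with the usual carotid-surgery baseline covariates
(age, blood pressure, lipids, BMI, eGFR, smoking, comorbidity histories,
medication, stenosis grades), the exposure, five dichotomized plaque
traits, IPH, 4-level symptom status, and a censored 3-year composite
endpoint.

**Exposure marginal.** Percent glycophorin is strictly positive and
right-skewed; per sex it follows a *two-piece (split) log-normal*,
`exp(μ + σ(z)·z)` with `z` standard normal, `μ = ln(median)` and separate
lower/upper scales `σ_lo = (ln med − ln q1)/Φ⁻¹(0.75)`,
`σ_hi = (ln q3 − ln med)/Φ⁻¹(0.75)`. The split form is used because the
configured male quartiles (7.15; 3.37–13.41 %) are asymmetric on the log
scale, which a single-σ log-normal anchored at the median cannot match;
the two σ's average to the usual IQR-based formula
`(ln q3 − ln q1)/(2×0.6745)`, and median, q1 and q3 are matched exactly.
Defaults: male 7.15 (3.37, 13.41) %, female 4.06 (1.98, 8.32) %,
29.8 % women.

**Confounding structure.** A standardized score over age, current smoking,
hypertension and eGFR is mixed into the exposure's latent normal with
correlation ρ = 0.18, *after* within-sex standardization — so the per-sex
exposure marginal stays exactly as configured while the screening step has
true positives (age, eGFR) and true negatives (e.g. diabetes, statins).
The same covariates (plus sex) carry direct effects on every outcome, so
Model 1 (plaque-size-only) is genuinely confounded and Model 2 is correctly
specified.

**Outcomes.** Binary outcomes are logistic in the within-cohort IRNT
exposure (per-1-SD slopes: IPH ln 1.90; symptoms ln 1.34, optionally
sex-specific ln 1.37 / ln 1.15; lipid core ln 1.85; macrophages ln 1.87;
calcifications ln 0.81; collagen ln 0.70; SMC ln 0.60), plus IRNT plaque
size (ln 1.20) and the confounder terms. Intercepts are solved by root
bracketing on a 100 000-draw Monte-Carlo sample of the linear predictor so
marginal prevalences hit their targets (IPH 62.4 %, symptomatic 87.1 %)
to within ±0.005; calibration is done once per configuration and reused
across replicate draws. The composite endpoint uses exponential event
times with log-hazard ln 1.14 per SD and a baseline rate calibrated to a
14 % 3-year cumulative incidence (a typical post-endarterectomy figure;
not an externally fixed constant), administratively censored at 3 years.
Dichotomized-trait prevalences default to 50 %. Missingness is injected
MCAR per column (rates ≤ 0.5; exposure, plaque size and outcomes are never
masked, so Model 1 is always estimable).

**Not emulated:** separate etiologies of the symptom subtypes, informative
missingness, non-proportional hazards, measurement error in the exposure,
or the selection process of a surgical biobank.

## 4. Transformations and descriptive statistics

* **IRNT** — average-rank ties, Blom offset:
  `Φ⁻¹((rank − 3/8)/(n + 1/4))`; strictly rank-preserving, invariant to
  monotone input transforms, missing values propagate. The Blom constant
  is the common biostatistics convention. Effects downstream are "per 1 SD"
  of this transform.
* **Log rule** — natural log applied when bias-corrected sample skewness
  exceeds 1.0 (requires positive values).
* **Descriptive tables** — mean (SD), or median (IQR) when |skew| > 1, for
  continuous variables with Wilcoxon rank-sum tests; n/N (%) with
  chi-square for categoricals, switching to Fisher's exact test for 2×2
  tables with any expected cell < 5 (r×c tables keep chi-square; scipy has
  no general exact test).
* **Group comparisons** — tie-corrected Kruskal–Wallis for the IPH
  contrast; all pairwise Wilcoxon tests for the 3-level phenotype
  contrast. All-identical input returns statistic 0, p 1.

## 5. Association pipeline

* **Screening** — candidate kept iff p < 0.1 in *both* (a) OLS of the
  SD-unit exposure on candidate + SD-unit plaque size (block F-test for
  multi-level candidates) and (b) a univariable logistic (or Cox, for the
  time-to-event endpoint) of the outcome on the candidate. Under a global
  null the selection probability per candidate is ≈ 0.1² = 0.01. Constant
  candidates are excluded with a warning. Screening runs on complete
  cases; final models on imputed data.
* **Imputation** — chained equations, default m = 10 copies × 20 sweeps.
  Every incomplete column is refit linearly on all others (categoricals as
  integer codes), coefficients are drawn from their approximate posterior,
  and missing entries are filled by predictive-mean matching with 5 donors
  — imputed values are always observed values, which handles binary and
  categorical columns naturally. Each copy runs on its own spawned RNG
  stream. Columns > 50 % missing are rejected.
* **Models** — per-1-SD logistic (statsmodels) and Cox proportional
  hazards (lifelines). Model 1 = exposure + plaque size; Model 2 adds the
  adjustment set. Across imputations, estimates are pooled by Rubin's
  rules with Barnard–Rubin-style degrees of freedom; with zero
  between-imputation variance the pooled fit equals the single fit.
  Perfect separation and non-convergence raise `ModelFitError` rather than
  returning silent estimates; |coef| > 15 on the logit scale is treated as
  separation. AIC = 2k − 2 lnL selects among candidate specifications,
  ties to the smaller model. Significance is two-sided 0.05 in final
  models, 0.1 in screening; no multiplicity correction is applied.
* **Stratification** — every main fit is repeated within men and women;
  strata under 50 subjects warn but still fit, and stratified results
  should be read against their (wider) confidence intervals.
* **Recovery harness** — generate → (mask → impute) → fit over R ≥ 100
  replicates; reports mean OR/HR, log-scale bias and SD, and 95 % CI
  coverage of the generating value. At n = 1819 with the default effects,
  mean recovered ratios sit within ±0.02 of the generating values and
  coverage is nominal. For recovery runs the Model 2 adjustment set is the
  generator's own (age, sex, smoking, hypertension, eGFR) — i.e. the
  correctly specified model — since the harness's purpose is to verify the
  estimator, not the screen.

## 6. Problem sizes and determinism

Test and acceptance runs use deliberately desk-scale inputs: slide canvases
of 256–768 px, 20-tile validation ladders at 320 px, 100–400 simulation
replicates, and single 100 000-row cohorts for marginal checks; these sizes
give Monte-Carlo error comfortably inside every stated tolerance. All
randomness is seeded through `numpy.random.SeedSequence` substreams; every
CLI command takes `--seed` and identical invocations produce identical
CSV/JSON outputs.

## 7. Known limitations

* The stain model assumes ideal Beer–Lambert mixing with the same vectors
  used for rendering and deconvolution; vector mismatch on real scanners
  will add bias that these tests cannot reveal.
* No hotspot-localization metric: the measure is location-agnostic by
  design, although the generator can produce hotspot truth for future work.
* The cohort simulator's covariates are mutually independent apart from the
  built-in confounder score and sex differences; real baseline tables are
  more strongly inter-correlated.
* MCAR missingness only; the imputer is linear-PMM and would understate
  uncertainty under strongly non-linear relationships.
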