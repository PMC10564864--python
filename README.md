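# glycoquant

Quantification of **glycophorin C immunostaining** in whole-slide images of
carotid atherosclerotic plaque, and the downstream association analysis that
relates the stained fraction to markers of plaque vulnerability.

Glycophorin C is an erythrocyte-specific membrane protein: the area of a
plaque section that stains positive for it marks accumulated erythrocytes and
erythrocyte membranes, a continuous readout of (past) intraplaque hemorrhage
(IPH). The package is aimed at vascular-histology and cardiovascular-epi
groups who want a reproducible, fully synthetic-testable implementation of
this measurement and its statistical pipeline:

* **Imaging arm** — tissue masking, tiling, H-DAB color deconvolution
  (Beer–Lambert, standard Ruifrok stain vectors), DAB-positive pixel
  counting, and aggregation to the per-slide measure

  $$\text{percent stain} = 100 \times \frac{\text{glycophorin-positive area }(\mu m^2)}{\text{total plaque area }(\mu m^2)},$$

  pooled over all tissue sections on the slide. A synthetic slide generator
  renders H-DAB-like sections with *pixel-exact* ground-truth masks
  (diffuse or hotspot staining patterns), so the whole chain is validated
  without any scanner data.

* **Statistical arm** — a calibrated synthetic patient cohort
  (n = 1819 by default, 29.8 % women, sex-specific percent-stain
  distributions with male median 7.15 (IQR 3.37–13.41) %), inverse-rank
  normal transformation of exposure and plaque size, confounder screening at
  p < 0.1 on both the exposure and outcome side, chained-equation imputation
  with Rubin pooling, and per-1-SD logistic / Cox models:
  Model 1 adjusts for plaque size, Model 2 for plaque size plus screened
  confounders, with AIC selection and sex stratification. A recovery harness
  verifies that the pipeline returns the generating odds/hazard ratios
  (e.g. OR 1.90 per SD for IPH, OR 1.34 for pre-procedural symptoms,
  HR 1.14 for 3-year MACE) without bias.

## Worked example

```bash
glycoquant synth-slides --out slides --n 3 --target-fractions 0.10,0.25,0.40 \
    --canvas 512 --seed 7
glycoquant quantify --slides slides --out quant.csv --tile-size 256
```

`quant.csv` then holds one row per slide:

```text
slide_id,stain_area_um2,plaque_area_um2,percent_stain,n_tiles_kept
slide_000,390.4375,3930.3125,9.9340065198378,4
slide_001,998.6875,3996.625,24.9882713539549,4
slide_002,1718.25,4304.5625,39.916948586528825,4
```

The recovered percentages (9.93 %, 24.99 %, 39.92 %) match the requested
ground-truth fractions (10 %, 25 %, 40 %) to well within the pipeline's
tolerance — areas are in μm² at the 0.25 μm/px calibration. The tile-ladder
validation and the parameter-recovery harness:

```bash
glycoquant validate-tiles --out tiles.csv --n 20 --tile-size 320 --seed 7
# Spearman rho (automated vs truth, 20 tiles): 1.0000
glycoquant recover --out recovery.json --replicates 100 --outcomes iph,symptomatic --seed 7
# iph: generating 1.900, mean recovered 1.913, coverage 0.97
# symptomatic: generating 1.340, mean recovered 1.357, coverage 0.93
```

The first line says automated stained-fraction estimates rank-correlate
perfectly with truth across a 0–50 % ladder; the last two say the Model 2
logistic fit recovers the generating per-SD odds ratios with near-nominal
95 % CI coverage over 100 simulated cohorts.

The same functionality is available as a library
(`glycoquant.synthesize_slide`, `glycoquant.quantify_slide`,
`glycoquant.CohortGenerator`, `glycoquant.run_recovery`, …); see
`docs/methods.md` for the model details and design choices.

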