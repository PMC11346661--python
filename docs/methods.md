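# Methods

`ripescan` implements a nondestructive fruit-quality assessment pipeline for
ripening cohorts of mandarin and tomato: biochemical assays from
spectrophotometer absorbance, color indices from photographs, spectral
reflectance indices from field-spectrometer curves, exhaustive two-band
ratio-index discovery, linear screening, and tree-model prediction of the
biochemical traits. Because no public measurement set accompanies the
underlying study design, the package ships a first-class synthetic cohort
generator that reproduces the statistical structure those analyses assume;
everything downstream is exercised end-to-end on it.

## Biochemical assays

Pigments are quantified from crude-extract absorbance by the classical
coefficient sets (A at 663, 645, 480, 503 nm; V = extract volume in mL,
W = fresh weight in g, units mg/g tissue except lycopene in µg/g):

- Chl a = (12.7·A663 − 2.69·A645) · V / (1000·W)
- Chl b = (22.9·A645 − 4.68·A663) · V / (1000·W)
- Carotenoids = (A480 + 0.114·A663 − 0.638·A645) · V / (1000·W)
- Lycopene = 3.121 · A503 · vol_sample · dilution / W

The carotenoid equation is sometimes typeset with a subtractive term
"(0.638 − A645)"; that form yields negative concentrations for ordinary
readings and contradicts the multiplicative convention of the coefficient
source, so the product form is the default and the subtractive form is kept
behind `variant="as_printed"` for auditability. Negative assay outputs are
reported with a warning, never clamped, so data problems stay visible.
The maturity index is TSS/TA (°Brix % over % citric-acid equivalents).

## RGB indices

Mean fruit color is extracted from photographs by masking pixels whose
grayscale mean exceeds a threshold (default 30/255; fruit on dark
background), then averaging each channel over the mask. The index catalog
operates on these mean channels. `Rn` is defined as R/(R+G+B): some
published tables print G in the numerator for "normalized red", but red
fruit with a rising red fraction across ripening is only consistent with
the R numerator; the G-numerator quantity is exposed as `Gn`. `ExG` (used
by `ExGR`) is the standard 2g−r−b on chromatic coordinates; `VARI1` is
evaluated on raw 0–255 channels, which is what reproduces its reported
0.5–1.0 magnitude. The two distinct normalized differences are kept under
separate keys (`NDVI1` = (R−B)/(R+B), identical to `IKAW`;
`NDVI_rgb` = (R−G)/(R+G), the negative of `GRVI`). Indices with a zero
denominator for a particular sample (e.g. VARI when G+R=B) are reported as
missing rather than ±inf.

## Spectral indices and the correlogram scan

Spectra live on the 302–1148 nm grid at 2 nm (424 points). Published
indices citing odd-nanometre bands are evaluated by linear interpolation
between bracketing grid points (nearest-neighbour lookup available). The
ratio spectral index is RSI(λ1, λ2) = R_λ1 / R_λ2.

The discovery scan regresses a trait on RSI(λ1, λ2) for *every ordered
pair* of grid wavelengths and stores the OLS R² in a matrix (the
"correlogram" or contour map). For a single predictor the OLS R² equals
the squared Pearson correlation, which is how the grid is computed —
vectorized over numerator wavelengths for one denominator at a time
(424×424 ≈ 180k regressions on the full grid run in seconds). The grid is
deliberately not symmetrized: trait ~ x and trait ~ 1/x are different
linear models with different R². Diagonal entries are missing by
convention (the index is constantly 1). Samples with a non-positive
denominator reflectance are dropped pairwise per regression; pairs with
fewer than 3 usable samples or a constant index are missing. Ranked best
pairs break R² ties by smaller band separation, then lexicographically.

## Screening

Trait–trait association is summarised by a pairwise-complete Pearson
matrix. The index–trait screen fits one simple OLS per (index, trait) and
reports R², the two-sided t-test p-value of the slope, and significance
stars at P ≤ 0.05/0.01/0.001. No multiple-testing correction is applied to
the stars (matching the conventional reporting of such screens); a
Bonferroni-adjusted p-value column is emitted alongside for transparency.

## Tree models, LOOCV and feature selection

Both model families come from scikit-learn: `DecisionTreeRegressor` (grid:
max depth Md ∈ {1,3,5,7,9}, min samples per leaf Ms ∈ {2,4,6,8,10}, max
leaf nodes Mln ∈ {None,10,20,30,40,50}, squared-error criterion) and
`RandomForestRegressor` (ntree ∈ 1..25, mtry ∈ 1..p, bootstrap, impurity
importances). Validation is leave-one-out over the 68-sample cohort; the
validation R²/RMSE use only the n held-out predictions, training metrics a
final fit on all data. RMSE = sqrt(mean squared error); R² = 1 − SSres/SStot
(a typeset variant of this statistic omitting the "1 −" would score a
perfect fit as 0 and is not offered). RF fits are reseeded
deterministically per fold from the base seed, so runs are reproducible.

Hyperparameters are tuned by exhaustive grid search minimising validation
RMSE; the grid is traversed simplest-first (shallower trees, larger
leaves, fewer trees) and only strict improvements replace the incumbent,
so ties resolve to the simpler configuration. The traversal uses exact
early abandonment: once a configuration's accumulated held-out squared
error exceeds the incumbent's total it cannot win and the remaining folds
are skipped — this changes nothing about the selected model or its
reported metrics, only the running time.

Feature selection ranks the full pool by the tuned model's impurity
importances (ties break by column order), then evaluates the nested top-k
subsets k = 1..p with re-tuning on each; the subset minimising validation
RMSE wins, ties preferring fewer features. Pools are the spectral catalog
(SRI), the RGB catalog (RGBI), and their column union (HV).

A deliberate property of this protocol: hyperparameters and features are
selected on the *same* LOOCV that is reported, so validation metrics carry
optimistic selection bias. That reproduces the historical protocol the
package models. `nested_loocv` wraps the entire selection in an outer
LOOCV for an honest generalisation estimate; it is the documented
deviation, not the default.

## The synthetic cohort generator

The generator emulates a 68-fruit-per-species ripening cohort — three
mandarin stages (unripe/ripe/overripe, allocation 23/23/22) and four
tomato stages (17 each). Per-stage trait means are the published stage
summaries for a Balady mandarin / Alissa F1 tomato series; standard
deviations use the normal-range heuristic sd = (max − min)/4 since only
range envelopes are published. Traits are drawn from positive-truncated
normals, except: Chl b is an affine function of the drawn Chl a (fit
through the stage means) plus 2% relative noise, reflecting the ~1.0
cohort correlation of the two co-degrading chlorophylls; and TSS/TA is
recomputed from the drawn TSS and TA, never drawn independently (a zero TA
draw is re-drawn). With the bundled profiles, mandarin stage means fall
across ripening for Chl a, Chl b and TA and rise for TSS, TSS/TA and
carotenoids; tomato follows its published stage means, in which TA *rises*
with ripening (and firmness falls, so the generated firmness–TA
correlation is negative).

Spectra come from a Beer–Lambert-style forward model:
`R(λ) = baseline(λ) · exp(−A(λ)) · nuisances · noise`, with

- baseline: a gentle logistic ramp from 0.72 (visible) to 0.82 (NIR);
- chlorophyll: optical depth 0.33 per unit load (Chl a + 0.5·Chl b) over a
  plateau bounded by logistic shoulders at 500 nm (green side, width 15)
  and 695 nm (the red edge, width 8), plus a small Soret Gaussian at
  430 nm;
- carotenoids: Gaussians at 450/480 nm (4.0 per mg/g); lycopene adds the
  same bands plus a 505 nm Gaussian (0.018 per µg/g);
- multiplicative lognormal noise, σ = 0.01 × `noise_scale`.

Four trait-independent per-sample nuisances emulate the biological
variability that real ratio-index screens contend with, each with a
physical analogue: a random shift of the pigment band edges (sd 2.5 nm,
red-edge position variability) and a lognormal rescaling of their widths
(edge-shape variability), a lognormally spread skin flavonoid/phenolic
absorber in the blue (proportional to the carotenoid level, so a
pigment-free sample stays absorption-free), a UV cuticle-screening factor
below ~430 nm, and a NIR internal-scattering albedo factor above ~755 nm.
Their joint effect is that the cleanest chlorophyll contrast available to
a two-band ratio lies between a red-edge-wing band (~700–760 nm) and a
visible absorption band (560–680 nm) — which is where the correlogram's
best pair lands, mirroring the red-edge/visible pairs that field studies
report. All structural constants are exposed in `SPECTRAL_SHAPE`.

Mean fruit color is derived from each spectrum by band-averaging
reflectance over 600–700 (R), 500–600 (G) and 400–500 nm (B), scaled to
0–255 and rounded to 2 decimals.

What the generator does *not* emulate: radiative-transfer realism
(no PROSPECT-style leaf/fruit optics), specular highlights or illumination
gradients in photographs (RGB fixtures are flat disks), instrument
artefacts (dark current, wavelength miscalibration), and measurement error
in the wet-lab traits themselves. Passing tests therefore demonstrate that
the analysis machinery recovers structure that is present by construction;
they do not certify performance on real instrument data.

## Numerical choices and degenerate inputs

- Reflectance is clipped to (0, 1.2); traits to [0, ∞).
- Constant traits abort a scan; constant indices yield missing entries.
- A correlogram λ_step must be a multiple of the acquisition step.
- R² of a constant target is an error (undefined), not 0 or 1.
- LOOCV requires n ≥ 3 and finite inputs.
- All randomness flows from explicit integer seeds; cohort, spectra and
  model paths are bit-reproducible for a fixed configuration.

## Problem sizes used in the bundled checks

The packaged tests and the `scripts/acceptance.py` summary use the default
study conditions: 68-sample cohorts, the full published hyperparameter
grids, the full 424-point spectral grid for catalog indices, an 8 nm scan
step for cohort-level correlograms (the full 2 nm scan is available and
used in the scan-oracle tests on small subgrids), and 1000 replicates for
the null calibration of the significance stars.

## Known limitations

- Validation metrics from the default protocol are optimistically biased
  (see above); use `nested_loocv` when an honest estimate matters.
- The RF grid (25 × p configurations × n folds) is expensive on large
  pools; the CLI's `--grid-preset fast` trades grid coverage for speed.
- The forward spectral model is a statistical emulator, not a physical
  model; its constants were chosen so the generator meets its documented
  contracts, and conclusions about real spectra require real data.
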