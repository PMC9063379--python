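# Methods

## Pipeline overview

For each plant the pipeline consumes ten rotational side-view RGB frames,
one hyperspectral cube and one steady-state fluorescence frame, and emits a
single row of fused predictors {R, G, B, H, S, I, NDVI, RVI, MCARI, Fluo}
plus the covariates DAS (days after sowing) and SLW (specific leaf weight,
g/cm²), against the response Chl (chlorophyll meter reading, µmol/m²).
All features are "specific leaf image" statistics: a channel summed over
plant pixels divided by the plant pixel count, i.e. a masked mean, averaged
across views.

## Colour processing

RGB values are normalized to [0, 1] and converted to HSI:

    H = arccos( [(R−G) + (R−B)] / 2 / sqrt((R−G)² + (R−B)(G−B)) ),
        reflected to 2π − H when B > G, then divided by 2π
    S = 1 − 3·min(R,G,B)/(R+G+B)
    I = (R+G+B)/3

Hue is set to 0 where undefined (achromatic pixels). Normalizing hue by 2π
before the colour index 3S/(H+S+I) is a deliberate choice: with
degree-valued hue the denominator would be dominated by H and a fixed
threshold near 1 would be meaningless. On the [0, 1] scale the index is
dimensionless and the default plant/background threshold of 0.75 applies
uniformly.

Segmentation: index ≥ 0.75, minus pixels matching an empty-chamber
reference frame (per-channel absolute difference below 0.02 — this removes
fixed chamber structure such as edge stripes that are themselves
high-index), then a 3×3 morphological opening and removal of 8-connected
components under 200 px. The leaf band keeps plant pixels whose row offset
from the plant top lies within [5 %, 35 %] of plant height (nearest-integer
rounding at both bounds, top = first row containing a plant pixel); this
band isolates leaves 2–4, the leaves against which the meter reference is
taken. Colour features use the band-restricted mask; projected area uses
the full plant mask — the plant-level definition of projected area — and
both are averaged over views.

## Hyperspectral processing

Cubes are band-interleaved-by-line (BIL) with an ENVI-style text header;
the reader supports the standard ENVI data-type codes and validates
header/payload consistency. Raw counts are calibrated to reflectance with
the two-reference formula R = (raw − dark)/(white − dark) per band and
sample, guarded where white = dark and clipped to [0, 1.5] to allow modest
sensor overshoot. Band lookup is by nearest wavelength in nm (ties to the
lower band) — never by fixed band indices, which depend on the exact
starting wavelength of a given camera. The default synthetic grid is 243
bands at 5 nm from 550 nm.

Segmentation uses the red edge: the 705 nm and 750 nm band images are each
min–max normalized over the frame, averaged, and thresholded at 0.89; the
mean-of-normalized combiner is used because it keeps a global threshold
scale-free (a `combiner="sum"` alternative is available). The same 200 px
component filter applies. The threshold operates on calibrated reflectance.

NDVI, RVI and MCARI are evaluated on the *mean* plant reflectance spectrum,
not averaged per-pixel indices; the two differ for heterogeneous plants and
the plant-level (specific-leaf-image) convention is the one used
throughout. The identity RVI = (1 + NDVI)/(1 − NDVI) is maintained to
machine precision and used as an internal consistency check.

## Fluorescence processing

Colour fluorescence frames are reduced to grayscale by the unweighted
channel mean (luminance weights are accepted as an option); segmentation
thresholds the intensity at 0.13 and applies the component filter. The
threshold can instead be calibrated from data: 50 frames are sampled
without replacement, 5 plant and 5 background positions per frame (500
positions total), and the threshold is placed at the midpoint of
[background maximum, plant minimum]; if the classes overlap, the
calibration reports non-separable with the overlap size rather than
guessing. The fluorescence feature is computed on the whole plant, not the
leaf band, matching whole-plant fluorescence analysis; a banded variant is
possible by passing banded masks.

## Models

**Per-feature MLR.** Chl = a₀ + a₁X + a₂·DAS and
Chl = b₀ + b₁X + b₂·DAS + b₃·SLW, ordinary least squares with an explicit
rank check. Model comparison uses the Gaussian AIC n·ln(RSS/n) + 2k with
k = number of coefficients + 1 (error variance); AIC is used only for
ranking — its absolute value is data-dependent. RSS = 0 maps to −∞ and is
flagged degenerate.

**Fused PLSR.** PLS1 by NIPALS with deflation of the predictor block only.
Predictors are standardized (zero mean, unit variance, with an explicit
zero-variance error naming the offending column) and the response is
centered; scaling the response would cancel in the predictions, so it is
not scaled. Coefficients are mapped back to the original predictor scale.
At full rank the predictions coincide with OLS, which is enforced in tests
against a normal-equations oracle and cross-checked against an independent
PLSR implementation. The component count is selected by stratified fivefold
cross-validation at the minimum mean CV MSE (ties to the smaller count),
and the final model is refit on all calibration rows; the full CV curve is
retained rather than fixing a component count a priori, since the optimal
count is data-dependent. Predictor importance is the descending order of
|standardized coefficient|, which supports dropping the least important
predictor (in practice hue) and refitting.

**Split and scoring.** The 80/20 calibration/validation split and the CV
folds are stratified by genotype × water × nutrient so every stratum is
represented on both sides (strata below 2 rows go wholly to calibration
with a warning). R² is the squared Pearson correlation between measured
and predicted — the definition that applies unchanged to validation data —
with 1 − RSS/TSS also reported; RMSE is the root mean squared prediction
error; RPD = SD(measured)/RMSE with the sample (ddof = 1) standard
deviation, infinite for perfect predictions.

## Synthetic study

The generator emulates the study design rather than any particular image
archive: 15 genotypes × 20 plants, 2×2 water (D/HW) × nutrient (HN/LN)
treatments with five replicates, each replicate imaged at one DAS from
{20, 30, 40, 50, 60}.

* **Chlorophyll trajectory**: Chl(DAS) = A_g · logistic((DAS − 25)/8), a
  minimal monotone rise-then-plateau; genotype asymptotes A_g ~ U(380, 560)
  µmol/m², additive shifts of −60 (drought) and −50 (low nutrition), and
  plant-level noise of sd 20 µmol/m². These effect sizes are a choice —
  made once, sized to give a realistic spread (SD ≈ 120–150 µmol/m² across
  the population) — not a calibration to any particular data set.
* **Meter emulation**: the measured value is the mean of nine spot
  readings, each true chlorophyll plus Gaussian noise of sd 15 µmol/m²
  (typical repeatability of handheld optical meters).
* **SLW**: 0.0045 g/cm² baseline, +0.0012 under drought (thicker, denser
  leaves), +0.0003 under low nutrition, noise sd 0.0004, floored at
  0.0005.
* **Geometry**: a stem plus six elliptical leaves, with leaves 2–4 inserted
  at 8 %, 18 % and 30 % of plant height so they sit inside the 5–35 % band;
  leaf lengths vary with view angle so projected area differs across the
  ten rotational views. The silhouette is itself morphologically open
  (a 3×3 opening is applied at construction), so the segmentation chain's
  opening is exactly the identity on noiseless scenes and mask recovery can
  be tested for exact equality. Plants taller than the frame are cropped,
  as by a real chamber camera.
* **Signal links** (all exported in closed form for testing):
  plant colour (R, G, B) = (g(1−s), g, g(1−s)) with s = 0.55 + 0.35·u and
  g = 0.45 − 0.06·u, u = clip(Chl/650, 0, 1) — saturation strictly
  increasing, greenness decreasing in chlorophyll; leaf reflectance
  R(λ) = R_vis + (0.55 − R_vis)·sigmoid((λ − 725)/8) with Beer–Lambert-type
  visible absorption R_vis = 0.08 + 0.42·exp(−Chl/300), making NDVI, RVI
  and MCARI strictly monotone in chlorophyll; fluorescence intensity
  0.25 + 0.5·u, exactly linear. Backgrounds are spectrally flat and darker
  than the plant in every contrast channel (optionally with warm-tinted
  vertical stripes to exercise reference-frame removal).
* **Noise model**: per-pixel Gaussian noise (sd 0.01 RGB, 0.002
  reflectance, 0.015 fluorescence) plus a per-plant, per-modality relative
  jitter of sd 0.10 applied to the chlorophyll value driving each
  modality's signal. Pixel noise averages out in masked means over
  thousands of pixels; the jitter is what limits single-channel model
  accuracy and makes the three modalities carry independent errors, so
  fusion genuinely helps.

**What passing tests show — and what they do not.** The synthetic scenes
have uniform leaf colour, no specular highlights, no occlusion, no soil or
pot in frame, and a perfectly known background. Exact mask recovery and
CV R² ≈ 0.98 on these scenes demonstrate that the formulas, thresholds,
filters and estimators are implemented correctly and that the method's
comparative structure (fusion ≥ single channel; adding SLW lowers AIC when
SLW carries signal; hue is dispensable when uninformative) reproduces.
They do not predict absolute accuracy on real greenhouse imagery, where
plant-level biological variation and segmentation errors are larger.

## Numerical choices and degenerate inputs

* Connected components use 8-connectivity; "fewer than 200 px" means
  components of exactly 200 px survive.
* Hue is 0 where undefined; the colour index is 0 where H + S + I = 0;
  reflectance is 0 where white = dark; constant band images raise a
  degenerate-frame error rather than dividing by zero.
* Zero-variance predictors are detected with a relative tolerance of 1e−12
  (a float-constant column has std ≈ 1e−16, not 0). In the exact zero-noise
  limit some image channels (e.g. hue of a fixed green) are constant across
  plants; the pipeline drops such columns with a warning before modeling.
* The NIPALS recursion stops early if the weight or score norm falls below
  1e−12, returning fewer components than requested.
* All randomness flows from explicit `numpy` generators seeded from a
  single run seed via CRC32-mixed, process-independent derived seeds; there
  is no global random state, and identical config + seed reproduces every
  output byte for byte.

## Problem sizes

Default synthetic frames are 256×256 (configurable up to full sensor
resolution); the test suite and the acceptance script run at 80–128 px
frames with 1–4 views and 16–300 plants, sizes at which every stage's
behaviour is already fully exercised and the complete suite runs in well
under a minute. The acceptance script processes the full 300-plant design
at 128×128.

## Known limitations

* The leaf-band heuristic assumes an upright plant with leaves 2–4 in a
  fixed height band; lodged or heavily curved plants would need instance
  segmentation, which is out of scope.
* The reflectance model is parametric and chlorophyll-driven only; water
  and structural absorption features above 800 nm are not emulated, and no
  PROSPECT-style radiative transfer is attempted.
* Fluorescence is steady-state intensity only; kinetic parameters (Fv/Fm)
  are not modelled.
* AIC values are comparable only within one data set; the pipeline reports
  them for ranking, never as absolute quality.
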