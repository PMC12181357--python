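# Methods

## Quantification model

The relative ellipsoid zone reflectivity (rEZR) is the ratio of the peak
linear reflectivity of the ellipsoid zone (EZ) to that of the external
limiting membrane (ELM), both measured on raw A-scans with intensities in
[0, 1] AU. The ELM serves as reference because it is a non-neural band
whose reflectivity is stable across eccentricities and early degeneration;
per-scan illumination multiplies both peaks and cancels in the ratio
(verified here to < 1e-9 relative error under random per-B-scan gains).

Per B-scan the chain is:

1. **Flattening.** Each column with a valid RPE row is shifted by an
   integer offset so the RPE lands on a common target row (the rounded
   median RPE row by default), with zero padding. Integer shifts are
   deliberate: sub-pixel interpolation would smooth the raw reflectivity
   values the ratio is defined on. Columns with missing RPE are left
   unshifted and excluded as `no_segmentation`.
2. **Profiles.** Adjoining, non-overlapping 9-column windows are averaged
   (arithmetic mean of linear intensities; max-aggregation was rejected as
   noise-amplifying) into axial reflectivity profiles. A narrower terminal
   window (e.g. the 3 leftover columns of a 768-column B-scan, 768 = 9·85
   + 3) is flagged and dropped.
3. **Peak windows.** EZ and ELM search windows, in pixels above the
   flattened RPE, are the two-sided normal-theory prediction intervals
   `mean ± t·sd·√(1+1/n)` of reference peak offsets (argmax inside broad
   anatomical bands, defaults 2–10 px for EZ and 11–22 px for ELM),
   rounded outward to whole pixels and clipped to the bands; at least 10
   reference profiles are required. The prediction interval is computed on
   peak *offsets*, not on full profile envelopes — the natural reading
   when the goal is to bound where a peak may sit.
4. **Peaks.** Inside each window the peak is the largest local maximum
   with prominence at least `k·noise` (default k = 2; noise estimated from
   the vitreous band above the ILM; absolute floor 1e-6 AU so a noise-free
   flat profile never yields a spurious peak). Plateau ties break toward
   the smaller offset (closer to the RPE) for reproducibility on discrete
   grids. A window without a qualifying maximum yields an absent flag.
5. **Ratio.** rEZR = EZ/ELM, reported as the plain linear-intensity ratio
   (configurable `scale_factor`, default 1); an absent peak or an ELM peak
   below 1e-6 AU excludes the ROI — never infinity.

Exclusions are tracked per cause and OR-ed: `drusen` where the
RPE-to-Bruch's-membrane separation strictly exceeds 15 px (≈ 100 µm) in
any column of the ROI; `atrophy` where either peak is absent (the
peak-absence criterion is the pipeline's only surrogate for geographic
atrophy / neovascularization — no morphological detection is attempted);
`no_segmentation` where any surface is missing.

## Geometry

The en-face map carries ROI-center coordinates relative to the fovea in µm
and in degrees of visual angle, using a configurable conversion of
288 µm/°, applied isotropically (the imaging literature uses values around
280–300 µm/°; no single value is canonical). Defaults mirror a 30°×25°
raster of 241 B-scans at 30 µm with 768 A-scans (lateral 11.25 µm/px) and
a 30°×30°, 768×768 px cSLO NIR frame (25.6 px/°).

The perimetry grid is 1 foveal point plus rings of 8 at 1°, 3°, 5° and 7°
(33 points), Goldmann III stimulus (0.43°), each sampled over twice the
stimulus diameter (0.86° disc). The azimuthal arrangement within rings is
not standardized; evenly spaced azimuths with a configurable rotation are
used and recorded in the grid object. Sampling uses an
ROI-center-in-disc rule (rather than area-weighted overlap) — simpler and
consistent at the map's ROI resolution; `coverage` is the included
fraction of ROI cells in the disc and points under `min_coverage = 0.5`
(partial-exclusion handling is not specified anywhere authoritative)
carry no value.

## Registration

The perimetry device's NIR image is cropped/resized to the cSLO frame,
then aligned with a classical intensity-based affine registration:
log-polar Fourier correlation for rotation/scale, phase correlation for
translation, and Levenberg–Marquardt least-squares refinement of all six
affine parameters on the intensity residual (images pre-smoothed, central
region subsampled). A normalized cross-correlation below 0.2 flags
failure, and sampling refuses to run on a failed transform; a two-channel
overlay is provided for visual QC. On noise-free synthetic pairs, random
similarity transforms (|shift| ≤ 30 px, rotation ≤ 5°, scale 0.95–1.05)
are recovered with mean control-point error ~1e-3 px.

## Phantom

The phantom renders each A-scan as a sum of Gaussian layer peaks (BM, RPE,
EZ, ELM, ILM) at integer rows, multiplied by a per-B-scan gain and clipped
to [0, 1], with optional additive truncated-Gaussian speckle (additive
rather than multiplicative gamma speckle: the goal is testability of the
detection chain, not physical speckle statistics). Default amplitudes put
the EZ/ELM template ratio at 0.74/0.02 = 37 AU, matching the magnitude of
mean global rEZR in mixed AMD/control cohorts; widths of 1 px and peak
separations ≥ 6 px keep Gaussian cross-talk below the 1e-6 relative
tolerance of the map-versus-truth oracle. Drusen are smooth quartic bumps
that raise the RPE (and the EZ/ELM riding on it) while Bruch's membrane
stays fixed, reproducing the separation-based exclusion geometry; atrophy
discs zero the EZ/ELM amplitudes. Truth surfaces equal the generating rows
exactly, and all randomness is seeded.

What the phantom does **not** emulate: multiplicative speckle statistics,
shadowing, segmentation error (truth surfaces are exact), vascular
structure in NIR images (a blob constellation plus pathology imprints
stands in), fixation instability, and the 4–2 threshold staircase.
Passing oracle tests therefore demonstrates correctness of the
computational chain under its stated model, not robustness to every
real-data artifact.

## Cohort simulation and association models

Point-wise sensitivity is generated as

```
y_ip = β0 + β_r·x_i(p) + β_age·age_i + β_male·male_i + stage_i
       + f(ecc_p) + u_i + e_ip,   clipped to [0, 36] dB
```

with a participant random intercept u_i (default sd 1.5 dB), residual
e_ip (default sd 2 dB), and a smooth foveal dip f(ecc) (default 2.5 dB,
scale 1.2°) reflecting reduced mesopic sensitivity at the fovea. The rEZR
exposure x can be attached at the point, 33-point-mean, or global level,
so each analysis level can be simulated with its own generating effect.
Participant rEZR means are drawn per stage from the distributions observed
in mixed cohorts (e.g. 47.8 ± 19.2 AU for controls, 16.3 ± 10.9 AU for
late AMD); local values add a linear eccentricity trend (1.5 AU/°,
consistent with lower central-subfield than global rEZR) and 8 AU
point-level scatter. Chart tests (BCVA, LLVA, MAT, Pelli-Robson) are drawn
from analogous linear predictors; the low-luminance deficit is derived as
BCVA − LLVA (the table-consistent convention; the alternative LLVA − BCVA
is selectable and recorded in metadata). Residual sds are chosen so the
[0, 36] dB clipping sits ≥ 3 sd from every stage mean and recovery is
unbiased.

The three estimators are OLS (global, locally averaged; stage entered as
three dummies against "no AMD", sex against "female") and a linear mixed
model (spatially resolved) with random intercept per participant, REML
estimation, normal-approximation CIs for fixed effects, and a natural
cubic regression spline in eccentricity with df = 3 and a centering
constraint (knots at quantiles; df and knot placement are not prescribed
anywhere authoritative, so they are surfaced in the API). Rank-deficient
designs raise an identifiability error naming the collinear columns.
No multiplicity adjustment is applied anywhere.

## Problem sizes and numerical choices

Tests and the acceptance script use reduced phantom rasters (15 B-scans ×
108 A-scans × 160 rows for oracles; 7 × 54 × 200 for the 100-phantom mask
sweep) — the quantification is per-column/per-ROI arithmetic, so
correctness does not depend on raster size. Monte-Carlo recovery uses 200
replicates of 275 eyes (33 points each for the mixed model), giving MC
standard errors of ~1–2% of each generating effect; recovery asserts
|bias| < 3 MC SE and empirical 95% CI coverage within [92%, 98%].
Registration recovery uses 50 random transforms. All random draws flow
from explicit seeds through `numpy.random.default_rng`; the quantification
itself is fully deterministic given its inputs.

## Known limitations

* Atrophy exclusion is purely peak-absence-based; real MNV/GA grading uses
  morphology and fundus autofluorescence.
* The classical registration assumes a global affine; it does not model
  eye-movement distortion within the raster or deformable differences
  between devices.
* The published clinical coefficient tables come from unreleased data;
  this package can demonstrate estimator correctness on simulations at
  those effect sizes, not reproduce the clinical fits themselves.
* The rEZR scale is the plain linear-intensity ratio; any fixed rescaling
  convention would divide all association coefficients accordingly (exact
  equivariance is tested).
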