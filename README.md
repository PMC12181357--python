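# ezreflect

Quantification of the **relative ellipsoid zone reflectivity (rEZR)** from
spectral-domain OCT volumes, and its association with retinal function in
age-related macular degeneration (AMD) — packaged as a tested, reusable
pipeline with a synthetic phantom/cohort generator so every stage can be
validated against known ground truth.

## The problem and the measure

The ellipsoid zone (EZ) is the hyperreflective OCT band attributed to
mitochondria in photoreceptor inner segments; its reflectivity degrades
with photoreceptor dysfunction before the band is frankly lost. Because raw
reflectivity depends on acquisition gain and media opacity, the EZ signal
is normalized to the external limiting membrane (ELM), a stable non-neural
reference band:

```
rEZR = EZ peak reflectivity / ELM peak reflectivity        [AU]
```

computed on raw, linear-intensity A-scans (dynamic range 0–1 AU), so that
per-scan illumination cancels in the ratio. Per B-scan the pipeline
straightens the image along the retinal pigment epithelium (RPE) with
integer column shifts, averages adjoining 9-pixel windows into axial
reflectivity profiles, searches for the EZ and ELM peaks inside windows
derived from the 95% prediction interval of reference peak offsets, and
forms the ratio. Regions with sub-RPE drusen (RPE-to-Bruch's-membrane
separation > 15 px, ≈ 100 µm), absent peaks (atrophy/neovascularization),
or missing segmentation are excluded with per-cause masks.

The en-face rEZR map is then related to retinal function at three levels:

* **global** — OLS of the mesopic average threshold (mesAT, dB, from
  33-point fundus-controlled perimetry) on the eye-wide mean rEZR,
  adjusted for AMD stage, age and sex;
* **locally averaged** — the same model with the mean rEZR over the 33
  stimulus points (sampled over twice the 0.43° Goldmann III stimulus
  diameter after affine registration of the perimetry NIR image to the
  cSLO NIR frame);
* **spatially resolved** — a linear mixed model of point-wise sensitivity
  on point-local rEZR with a per-participant random intercept and a
  natural cubic spline in eccentricity, fitted by REML.

## Worked example

```python
import ezreflect as ez

# a synthetic eye: curved RPE, one druse, one atrophic disc, no noise
params = ez.PhantomParams(
    n_bscans=15, ascans_per_bscan=108, rows_per_ascan=160,
    curvature_amplitude=8.0,
    drusen_spec=((30.0, 4.0, 12.0, 22.0),),
    atrophy_spec=((80.0, 11.0, 9.0),),
)
volume, truth = ez.generate_volume(params, seed=11)
rezr_map = ez.compute_map(volume, truth.surfaces)
print(f"global rEZR {rezr_map.global_mean():.2f} AU, "
      f"{int(rezr_map.included.sum())}/{rezr_map.values.size} ROIs included")

# association on a simulated cohort (generating effect 0.0065 dB/AU)
cohort = ez.simulate_cohort(ez.CohortConfig(n_participants=275, seed=3))
print(ez.fit_spatial(cohort).summary())
```

Output:

```
global rEZR 37.00 AU, 160/180 ROIs included
Association model (LMM (REML)); outcome: sensitivity_db
n_observations=9075, n_participants=275, converged=True
predictor                                 CE                    95% CI         p
Intercept                              33.81           [ 32.02,  35.6]5.926e-300
...
rezr                                 0.00573     [ 0.001004,  0.01046]   0.01749
...
random_intercept_var: 1.815
```

The phantom's EZ/ELM template ratio is 0.74/0.02 = 37 AU, recovered exactly
outside the drusen/atrophy exclusions (20 of 180 ROI cells here); the
mixed-model coefficient estimate for rEZR in one simulated cohort
(0.0057 dB/AU, 95% CI 0.0010–0.0105) scatters around the generating
0.0065 dB/AU, with the cohort's between-eye heterogeneity absorbed by the
random intercept.

A command-line pipeline mirrors the library:

```
ezreflect simulate --out-dir run --seed 1
ezreflect quantify --volume run/volume.tif --surfaces run/surfaces.csv --out-dir run/q
ezreflect align --cslo run/cslo_nir.tif --fcp run/fcp_nir.tif --map run/q/rezr_map.csv --out-dir run/a
ezreflect analyze --cohort-dir run/cohort --out-dir run/m
ezreflect report --map run/q/rezr_map.csv --samples run/a/aligned_samples.csv --out run/report.png
```

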