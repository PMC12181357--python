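"""Simulation-based validation harnesses.

These routines exercise the full pipeline against the phantom's known
ground truth: gain-invariance of the rEZR ratio, drusen-mask equivalence
with a brute-force separation scan, known-transform registration recovery,
noise-free oracle equivalence of the en-face map, and parameter recovery of
the three association-model levels at stated generating effect sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import association, phantom, quantify, structfunc

_MOD = 2**31


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k * 7919 + 17) % _MOD


# ---------------------------------------------------------------------------
# quantification oracles
# ---------------------------------------------------------------------------


def default_validation_params(**overrides) -> phantom.PhantomParams:
    base = dict(
        n_bscans=15,
        ascans_per_bscan=108,
        rows_per_ascan=160,
        curvature_amplitude=8.0,
        drusen_spec=((30.0, 4.0, 12.0, 22.0),),
        atrophy_spec=((80.0, 11.0, 9.0),),
    )
    base.update(overrides)
    return phantom.PhantomParams(**base)


def noise_free_map_error(seed: int = 0) -> dict:
    """Max relative error of the computed map vs generator truth, outside
    exclusions, on a noise-free phantom."""
    params = default_validation_params()
    volume, truth = phantom.generate_volume(params, seed=seed)
    m = quantify.compute_map(volume, truth.surfaces)
    inc = m.included
    expected = params.layers["EZ"].amplitude / params.layers["ELM"].amplitude
    rel = np.abs(m.values[inc] - expected) / expected
    return {"max_rel_err": float(rel.max()), "n_rois": int(inc.sum())}


def gain_invariance_error(n_fields: int = 20, seed: int = 0) -> dict:
    """Max relative rEZR change over random positive per-B-scan gain fields.

    Gains are drawn in [0.3, 1.1] so gained intensities stay inside the
    instrument's [0, 1] AU range (saturation would clip the peaks and void
    the ratio identity by construction, not by algorithm).
    """
    volume, truth = phantom.generate_volume(default_validation_params(), seed=seed)
    base = quantify.compute_map(volume, truth.surfaces)
    inc = base.included
    rng = np.random.default_rng(_derive_seed(seed, 1))
    worst = 0.0
    for _ in range(n_fields):
        gains = rng.uniform(0.3, 1.1, volume.n_bscans)
        gained = quantify.OCTVolume(
            volume.intensities * gains[:, None, None],
            axial_scale=volume.axial_scale,
            lateral_scale=volume.lateral_scale,
            bscan_spacing=volume.bscan_spacing,
            fovea_center=volume.fovea_center,
        )
        m = quantify.compute_map(gained, truth.surfaces)
        if not np.array_equal(m.included, inc):
            return {"max_rel_err": float("inf"), "n_fields": n_fields}
        rel = np.abs(m.values[inc] - base.values[inc]) / base.values[inc]
        worst = max(worst, float(rel.max()))
    return {"max_rel_err": worst, "n_fields": n_fields}


def drusen_mask_oracle(n_phantoms: int = 100, seed: int = 0) -> dict:
    """Mismatched ROI cells between mask_drusen and an independent
    brute-force per-column RPE-BM separation scan, over random phantoms;
    also verifies threshold monotonicity."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    monotone_violations = 0
    cells = 0
    for k in range(n_phantoms):
        n_drusen = int(rng.integers(0, 4))
        spec = tuple(
            (
                float(rng.uniform(5, 49)),
                float(rng.uniform(1, 6)),
                float(rng.uniform(4, 15)),
                float(rng.uniform(5, 30)),
            )
            for _ in range(n_drusen)
        )
        params = phantom.PhantomParams(
            n_bscans=7, ascans_per_bscan=54, rows_per_ascan=200, drusen_spec=spec
        )
        _, truth = phantom.generate_volume(params, seed=_derive_seed(seed, k))
        surf = truth.surfaces
        flags = quantify.mask_drusen(surf, threshold_px=15, window=9).flags
        sep = surf.layer("BM") - surf.layer("RPE")
        brute = np.zeros_like(flags)
        for b in range(sep.shape[0]):
            for i in range(flags.shape[1]):
                for x in range(i * 9, (i + 1) * 9):
                    if np.isfinite(sep[b, x]) and sep[b, x] > 15:
                        brute[b, i] = True
        mismatches += int((flags != brute).sum())
        cells += flags.size
        tighter = quantify.mask_drusen(surf, threshold_px=20, window=9).flags
        monotone_violations += int((tighter & ~flags).sum())
    return {
        "mismatched_cells": mismatches,
        "monotone_violations": monotone_violations,
        "cells_checked": cells,
        "n_phantoms": n_phantoms,
    }


# ---------------------------------------------------------------------------
# registration recovery
# ---------------------------------------------------------------------------


def registration_recovery(
    n_affines: int = 50,
    seed: int = 0,
    max_shift: float = 30.0,
    max_rotation_deg: float = 5.0,
    scale_range: tuple[float, float] = (0.95, 1.05),
) -> dict:
    """Mean control-point error recovering random similarity transforms on
    noise-free phantom NIR pairs (5x5 control grid over the central half)."""
    _, truth = phantom.generate_volume(default_validation_params(), seed=seed)
    rng = np.random.default_rng(_derive_seed(seed, 2))
    c = (768 - 1) / 2.0
    grid = np.stack(
        np.meshgrid(np.linspace(192, 575, 5), np.linspace(192, 575, 5)), -1
    ).reshape(-1, 2)
    errors = []
    for k in range(n_affines):
        th = math.radians(rng.uniform(-max_rotation_deg, max_rotation_deg))
        s = rng.uniform(*scale_range)
        t = rng.uniform(-max_shift, max_shift, 2)
        R = s * np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        tvec = t + np.array([c, c]) - R @ np.array([c, c])
        A = np.hstack([R, tvec[:, None]])
        pair = phantom.render_nir_pair(truth, A, seed=_derive_seed(seed, 100 + k))
        tf = structfunc.register(pair.cslo, pair.fcp)
        true_pts = grid @ A[:, :2].T + A[:, 2]
        errors.append(float(np.linalg.norm(tf.apply(grid) - true_pts, axis=1).mean()))
    return {
        "mean_cpe_px": float(np.mean(errors)),
        "max_cpe_px": float(np.max(errors)),
        "n_affines": n_affines,
    }


# ---------------------------------------------------------------------------
# association-model parameter recovery
# ---------------------------------------------------------------------------

#: per-level generating models: the rEZR effect (the recovery truth) is
#: attached at the level's exposure; the remaining fixed effects follow the
#: corresponding multivariable-model column (or none, for the univariate
#: marginal model)
RECOVERY_LEVELS = {
    "global": dict(
        truth=0.0492,
        config=dict(
            rezr_effect_level="global",
            effect_beta_rezr=0.0492,
            intercept=29.5041,
            effect_beta_age=-0.0906,
            effect_beta_male=-0.6307,
            stage_offsets={
                "no AMD": 0.0,
                "early": -0.9677,
                "intermediate": -1.3611,
                "late": -15.2023,
            },
        ),
    ),
    "local_avg": dict(
        truth=0.0247,
        config=dict(
            rezr_effect_level="participant_mean",
            effect_beta_rezr=0.0247,
            intercept=31.3301,
            effect_beta_age=-0.1066,
            effect_beta_male=-0.6807,
            stage_offsets={
                "no AMD": 0.0,
                "early": -0.9375,
                "intermediate": -1.2205,
                "late": -15.2388,
            },
        ),
    ),
    "spatial": dict(
        truth=0.0065,
        config=dict(
            rezr_effect_level="point",
            effect_beta_rezr=0.0065,
            intercept=34.7798,
            effect_beta_age=-0.1303,
            effect_beta_male=-0.7716,
            stage_offsets={
                "no AMD": 0.0,
                "early": -1.1150,
                "intermediate": -1.5605,
                "late": -16.2982,
            },
        ),
    ),
    "univariate_global": dict(
        truth=0.1787,
        config=dict(
            rezr_effect_level="global",
            effect_beta_rezr=0.1787,
            intercept=15.2,
            effect_beta_age=0.0,
            effect_beta_male=0.0,
            stage_offsets={s: 0.0 for s in phantom.STAGES},
        ),
    ),
}


def _fit_level(level: str, cohort):
    if level == "global":
        return association.fit_global(cohort)
    if level == "local_avg":
        return association.fit_local_avg(cohort)
    if level == "spatial":
        return association.fit_spatial(cohort)
    if level == "univariate_global":
        return association.fit_univariate(cohort.participants, "global_rezr", "mesat_db")
    raise ValueError(f"unknown level {level!r}")


def recover_effect(
    level: str,
    n_participants: int = 275,
    replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Simulate at the level's generating truth and re-estimate it.

    Returns the Monte-Carlo mean estimate, its MC standard error, the bias,
    and the empirical 95% CI coverage across replicates.
    """
    spec = RECOVERY_LEVELS[level]
    truth = spec["truth"]
    estimates, covered = [], 0
    for r in range(replicates):
        cfg = phantom.CohortConfig(
            n_participants=n_participants,
            seed=_derive_seed(seed, 10_000 + r),
            **spec["config"],
        )
        cohort = phantom.simulate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _fit_level(level, cohort)
        row = res.rezr
        estimates.append(float(row["estimate"]))
        if row["ci_low"] <= truth <= row["ci_high"]:
            covered += 1
    estimates = np.asarray(estimates)
    return {
        "truth": truth,
        "mean_estimate": float(estimates.mean()),
        "sd_estimate": float(estimates.std(ddof=1)),
        "mc_se": float(estimates.std(ddof=1) / math.sqrt(replicates)),
        "bias": float(estimates.mean() - truth),
        "coverage": covered / replicates,
        "replicates": replicates,
        "n_participants": n_participants,
    }
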