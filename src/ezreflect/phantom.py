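"""Synthetic OCT phantom and cohort generator with known ground truth.

Every downstream stage (flattening, peak detection, exclusion masking,
registration, association models) is validated against this module: it
renders raster volumes as sums of Gaussian layer peaks at known surface
positions, deforms the RPE with drusen while Bruch's membrane stays fixed,
zeroes the EZ/ELM amplitudes inside atrophic discs, applies per-B-scan
illumination gain and additive speckle, and simulates participant cohorts
whose point-wise retinal sensitivities follow a stated linear model with a
configurable rEZR effect.

Geometry and intensity conventions mirror a 30 x 25 degree Spectralis-like
raster (241 B-scans at 30 um, 768 A-scans of 496 rows, linear intensities
in [0, 1] AU).  The EZ/ELM template amplitude ratio defaults to
0.74 / 0.02 = 37 AU, matching the magnitude of population mean global rEZR
values reported for mixed AMD/control cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import skimage.transform

from .association import derive_lld
from .quantify import (
    DEGREES_TO_UM,
    LATERAL_SCALE_UM,
    AXIAL_SCALE_UM,
    OCTVolume,
    SegmentationSurfaces,
)
from .structfunc import make_grid

STAGES = ("no AMD", "early", "intermediate", "late")


# ---------------------------------------------------------------------------
# volume phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerPeak:
    """One reflective band: offset above the RPE (px, positive = shallower),
    Gaussian amplitude (AU) and width (px)."""

    name: str
    offset_above_rpe: float
    amplitude: float
    width: float


#: layer template whose EZ/ELM amplitude ratio is 37 AU; peak separations of
#: at least 6 px at width 1 px keep Gaussian cross-talk below 1e-6 relative
DEFAULT_LAYER_TEMPLATE = (
    LayerPeak("BM", -10.0, 0.35, 1.0),
    LayerPeak("RPE", 0.0, 0.88, 1.0),
    LayerPeak("EZ", 7.0, 0.74, 1.0),
    LayerPeak("ELM", 14.0, 0.02, 1.0),
    LayerPeak("ILM", 90.0, 0.15, 1.0),
)


@dataclass
class PhantomParams:
    """Geometry, optics and pathology of one synthetic volume.

    ``drusen_spec`` entries are ``(center_ascan, center_bscan, radius_px,
    height_px)`` bumps that push the RPE (and the EZ/ELM riding on it)
    upward while BM stays fixed; ``atrophy_spec`` entries are
    ``(center_ascan, center_bscan, radius_px)`` discs where the EZ and ELM
    amplitudes are zero.  Radii are in A-scan pixels and applied
    isotropically in micrometres across B-scans.
    """

    n_bscans: int = 241
    ascans_per_bscan: int = 768
    rows_per_ascan: int = 496
    bscan_spacing: float = 30.0
    lateral_scale: float = LATERAL_SCALE_UM
    axial_scale: float = AXIAL_SCALE_UM
    degrees_to_um: float = DEGREES_TO_UM
    layer_template: tuple[LayerPeak, ...] = DEFAULT_LAYER_TEMPLATE
    curvature_amplitude: float = 0.0
    drusen_spec: tuple[tuple[float, float, float, float], ...] = ()
    atrophy_spec: tuple[tuple[float, float, float], ...] = ()
    speckle_sd: float = 0.0
    gain_range: tuple[float, float] = (1.0, 1.0)
    rpe_base_row: int | None = None
    drusen_threshold_px: float = 15.0

    def __post_init__(self) -> None:
        for name in ("n_bscans", "ascans_per_bscan", "rows_per_ascan"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("bscan_spacing", "lateral_scale", "axial_scale", "degrees_to_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        by_name = {p.name: p for p in self.layer_template}
        if set(by_name) != {"ILM", "ELM", "EZ", "RPE", "BM"}:
            raise ValueError("layer_template must name ILM, ELM, EZ, RPE, BM")
        for p in self.layer_template:
            if not 0.0 <= p.amplitude <= 1.0:
                raise ValueError(f"{p.name} amplitude outside [0, 1]")
            if p.width <= 0:
                raise ValueError("peak widths must be positive")
        o = {k: v.offset_above_rpe for k, v in by_name.items()}
        if not (o["BM"] < o["RPE"] == 0.0 < o["EZ"] < o["ELM"] < o["ILM"]):
            raise ValueError("offsets must satisfy BM < RPE(=0) < EZ < ELM < ILM")
        if self.speckle_sd < 0:
            raise ValueError("speckle_sd must be >= 0")
        g0, g1 = self.gain_range
        if not (0 < g0 <= g1):
            raise ValueError("gain_range must be a positive interval")
        for cx, cb, r, h in self.drusen_spec:
            if h < 0:
                raise ValueError("drusen height must be >= 0")
            if r <= 0:
                raise ValueError("drusen radius must be positive")
            if not (0 <= cx < self.ascans_per_bscan and 0 <= cb < self.n_bscans):
                raise ValueError("drusen center outside the en-face frame")
        for cx, cb, r in self.atrophy_spec:
            if r <= 0:
                raise ValueError("atrophy radius must be positive")
            if not (0 <= cx < self.ascans_per_bscan and 0 <= cb < self.n_bscans):
                raise ValueError("atrophy center outside the en-face frame")

    @property
    def layers(self) -> dict[str, LayerPeak]:
        return {p.name: p for p in self.layer_template}


@dataclass
class PhantomTruth:
    """Generating ground truth for one phantom volume (synthetic oracle)."""

    surfaces: SegmentationSurfaces
    true_rezr_map: np.ndarray  # (n_bscans, n_ascans); NaN inside atrophy
    drusen_mask_truth: np.ndarray  # bool (n_bscans, n_ascans)
    atrophy_mask_truth: np.ndarray  # bool (n_bscans, n_ascans)
    applied_gains: np.ndarray  # (n_bscans,)
    params: PhantomParams | None = None

    def __post_init__(self) -> None:
        shape = self.true_rezr_map.shape
        if self.drusen_mask_truth.shape != shape or self.atrophy_mask_truth.shape != shape:
            raise ValueError("truth arrays must share en-face dimensions")
        if np.nanmin(self.true_rezr_map) < 0:
            raise ValueError("true_rezr_map must be >= 0")


def _enface_dist2(params: PhantomParams, cx: float, cb: float, radius: float):
    """Squared normalized en-face distance; isotropic in micrometres."""
    x = np.arange(params.ascans_per_bscan, dtype=float)
    b = np.arange(params.n_bscans, dtype=float)
    rb = radius * params.lateral_scale / params.bscan_spacing
    dx = (x[None, :] - cx) / radius
    db = (b[:, None] - cb) / rb
    return dx * dx + db * db


def generate_volume(params: PhantomParams, seed: int) -> tuple[OCTVolume, PhantomTruth]:
    """Render a phantom volume and its exact generating truth.

    Each A-scan is the sum of Gaussian layer peaks at the (curved,
    drusen-displaced, integer-rounded) surface rows, multiplied by the
    per-B-scan gain, plus additive speckle, clipped to [0, 1].  The returned
    truth surfaces equal the generating rows exactly.
    """
    rng = np.random.default_rng(seed)
    B, W, R = params.n_bscans, params.ascans_per_bscan, params.rows_per_ascan
    layers = params.layers

    base = params.rpe_base_row if params.rpe_base_row is not None else int(R * 0.7)
    xn = np.linspace(-1.0, 1.0, W) if W > 1 else np.zeros(1)
    bn = np.linspace(-1.0, 1.0, B) if B > 1 else np.zeros(1)
    bowl = (xn[None, :] ** 2 + bn[:, None] ** 2) / 2.0
    rpe_smooth = base + params.curvature_amplitude * bowl

    bump = np.zeros((B, W))
    for cx, cb, r, h in params.drusen_spec:
        d2 = _enface_dist2(params, cx, cb, r)
        inside = d2 < 1.0
        bump += np.where(inside, h * (1.0 - d2) ** 2, 0.0)

    atrophy = np.zeros((B, W), dtype=bool)
    for cx, cb, r in params.atrophy_spec:
        atrophy |= _enface_dist2(params, cx, cb, r) < 1.0

    rows = {}
    rows["BM"] = np.round(rpe_smooth - layers["BM"].offset_above_rpe)
    rpe = np.round(rpe_smooth - bump)
    rows["RPE"] = rpe
    for name in ("EZ", "ELM", "ILM"):
        rows[name] = np.round(rpe - layers[name].offset_above_rpe)
    for name, arr in rows.items():
        if arr.min() < 0 or arr.max() >= R:
            raise ValueError(f"{name} surface leaves the A-scan row range")

    gains = rng.uniform(params.gain_range[0], params.gain_range[1], size=B)

    amp_ez = np.where(atrophy, 0.0, layers["EZ"].amplitude)
    amp_elm = np.where(atrophy, 0.0, layers["ELM"].amplitude)
    const_amps = {name: layers[name].amplitude for name in ("BM", "RPE", "ILM")}

    depth = np.arange(R, dtype=float)
    vol = np.empty((B, R, W))
    for b in range(B):
        img = np.zeros((R, W))
        for name, amp in const_amps.items():
            lp = layers[name]
            img += amp * np.exp(
                -((depth[:, None] - rows[name][b][None, :]) ** 2) / (2.0 * lp.width**2)
            )
        for name, amps in (("EZ", amp_ez), ("ELM", amp_elm)):
            lp = layers[name]
            img += amps[b][None, :] * np.exp(
                -((depth[:, None] - rows[name][b][None, :]) ** 2) / (2.0 * lp.width**2)
            )
        img *= gains[b]
        if params.speckle_sd > 0:
            img += rng.normal(0.0, params.speckle_sd, size=img.shape)
        vol[b] = img
    np.clip(vol, 0.0, 1.0, out=vol)

    with np.errstate(invalid="ignore"):
        true_map = np.where(
            atrophy, np.nan, layers["EZ"].amplitude / layers["ELM"].amplitude
        )
    truth = PhantomTruth(
        surfaces=SegmentationSurfaces(rows={k: v.astype(float) for k, v in rows.items()}),
        true_rezr_map=true_map,
        drusen_mask_truth=(rows["BM"] - rows["RPE"]) > params.drusen_threshold_px,
        atrophy_mask_truth=atrophy,
        applied_gains=gains,
        params=params,
    )
    fovea = (B // 2, W // 2)
    volume = OCTVolume(
        intensities=vol,
        axial_scale=params.axial_scale,
        lateral_scale=params.lateral_scale,
        bscan_spacing=params.bscan_spacing,
        fovea_center=fovea,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# en-face NIR pair
# ---------------------------------------------------------------------------


def render_nir_texture(truth: PhantomTruth, seed: int, size: int = 768) -> np.ndarray:
    """Deterministic en-face NIR-like texture: smooth blob constellation plus
    imprints of the phantom's drusen elevation and atrophy discs."""
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:size, 0:size].astype(float)
    img = np.full((size, size), 0.45)
    for _ in range(40):
        cx, cy = rng.uniform(0, size, 2)
        sigma = rng.uniform(10, 40)
        amp = rng.uniform(-0.15, 0.15)
        img += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
    elev = truth.surfaces.layer("BM") - truth.surfaces.layer("RPE")
    if elev.max() > 0:
        elev = elev / elev.max()
    img += 0.2 * skimage.transform.resize(elev, (size, size), order=1, anti_aliasing=False)
    img += 0.25 * skimage.transform.resize(
        truth.atrophy_mask_truth.astype(float), (size, size), order=1, anti_aliasing=False
    )
    return np.clip(img, 0.0, 1.0)


@dataclass
class NIRPair:
    """A cSLO NIR image and its FCP-device counterpart with the true warp."""

    cslo: np.ndarray
    fcp: np.ndarray
    true_affine: np.ndarray  # 2x3, maps FCP (30 deg/768 px frame) -> cSLO px
    fcp_fov: float = 30.0
    fcp_size: int = 768


def render_nir_pair(
    truth: PhantomTruth,
    affine: np.ndarray,
    seed: int,
    noise_sd: float = 0.0,
    fcp_size: int = 768,
    fcp_fov: float = 30.0,
    size: int = 768,
) -> NIRPair:
    """Render a cSLO NIR image and the FCP-frame image warped by ``affine``.

    ``affine`` is a 2x3 matrix mapping coordinates in the canonical FCP
    frame (30 deg over 768 px, (x, y) = (col, row)) to cSLO pixel
    coordinates: ``fcp(p) = cslo(A p)``.  The FCP image may be rendered in a
    different frame (``fcp_fov`` degrees over ``fcp_size`` px); independent
    Gaussian noise of ``noise_sd`` is added to it.
    """
    A = np.asarray(affine, dtype=float)
    if A.shape == (3, 3):
        A = A[:2]
    if A.shape != (2, 3):
        raise ValueError("affine must be 2x3 (or 3x3 homogeneous)")
    if abs(np.linalg.det(A[:, :2])) < 1e-12:
        raise ValueError("affine is degenerate (non-invertible)")

    cslo = render_nir_texture(truth, seed, size=size)

    # frame change: FCP-device px -> canonical 30 deg / 768 px FCP frame
    scale = (fcp_fov / fcp_size) / (30.0 / size)
    c_dev = (fcp_size - 1) / 2.0
    c_can = (size - 1) / 2.0
    S = np.array([[scale, 0.0, c_can - scale * c_dev], [0.0, scale, c_can - scale * c_dev]])
    H = np.vstack([A, [0.0, 0.0, 1.0]]) @ np.vstack([S, [0.0, 0.0, 1.0]])
    tform = skimage.transform.AffineTransform(matrix=H)
    fcp = skimage.transform.warp(
        cslo, tform, output_shape=(fcp_size, fcp_size), order=3, mode="reflect"
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed + 1)
        fcp = np.clip(fcp + rng.normal(0.0, noise_sd, fcp.shape), 0.0, 1.0)
    return NIRPair(cslo=cslo, fcp=fcp, true_affine=A, fcp_fov=fcp_fov, fcp_size=fcp_size)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


#: per-stage global rEZR distributions (mean, sd in AU) of the kind reported
#: for control / early / intermediate / late AMD groups
DEFAULT_REZR_STAGE_PARAMS = {
    "no AMD": (47.8, 19.2),
    "early": (41.2, 17.3),
    "intermediate": (36.9, 16.7),
    "late": (16.3, 10.9),
}

#: chart-test generating models: intercept, beta_rezr (per AU of global
#: rEZR), per-stage offsets, beta_age (per year), beta_male, residual sd
DEFAULT_CHART_MODELS = {
    "bcva": (-0.2756, -0.0006, (0.0, 0.0293, 0.0448, 0.7612), 0.0040, -0.0173, 0.08),
    "llva": (-0.1465, -0.0015, (0.0, 0.0212, 0.0669, 0.7102), 0.0053, -0.0046, 0.10),
    "mat": (0.0202, -0.0011, (0.0, 0.0301, 0.0557, 0.6022), 0.0059, -0.0282, 0.12),
    "pr": (1.7991, 0.0030, (0.0, -0.0438, -0.1071, -0.5043), -0.0035, 0.0127, 0.15),
}


@dataclass
class CohortConfig:
    """Generating model for a synthetic participant cohort.

    Point-wise sensitivity (dB) is::

        intercept + beta_rezr * x + beta_age * age + beta_male * male
        + stage_offset + f(ecc) + u_i + e_ip,   clipped to [0, 36]

    where ``x`` is, per ``rezr_effect_level``, the point-local rEZR
    ("point"), the participant's 33-point mean ("participant_mean"), or the
    participant's global rEZR ("global"); ``f(ecc)`` is a smooth foveal dip;
    ``u_i`` is a participant random intercept and ``e_ip`` residual noise.
    """

    n_participants: int = 80
    stage_probabilities: dict[str, float] = field(
        default_factory=lambda: {
            "no AMD": 53 / 275,
            "early": 34 / 275,
            "intermediate": 152 / 275,
            "late": 36 / 275,
        }
    )
    age_distribution: tuple[float, float] = (71.1, 7.2)
    sex_probability_female: float = 0.633
    effect_beta_rezr: float = 0.0065
    effect_beta_age: float = -0.1303
    effect_beta_male: float = -0.7716
    stage_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "no AMD": 0.0,
            "early": -1.1150,
            "intermediate": -1.5605,
            "late": -16.2982,
        }
    )
    intercept: float = 34.7798
    random_intercept_sd: float = 1.5
    residual_sd: float = 2.0
    sensitivity_range: tuple[float, float] = (0.0, 36.0)
    rezr_effect_level: str = "point"
    rezr_stage_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REZR_STAGE_PARAMS)
    )
    rezr_ecc_slope: float = 1.5  # AU per degree of eccentricity
    rezr_point_sd: float = 8.0  # AU, within-eye point-to-point scatter
    ecc_dip_db: float = 2.5  # mesopic foveal sensitivity dip, dB
    ecc_dip_scale_deg: float = 1.2
    chart_models: dict = field(default_factory=lambda: dict(DEFAULT_CHART_MODELS))
    lld_convention: str = "table1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        total = sum(self.stage_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("stage probabilities must sum to 1")
        if set(self.stage_probabilities) != set(STAGES):
            raise ValueError(f"stage probabilities must cover {STAGES}")
        for name in ("random_intercept_sd", "residual_sd", "rezr_point_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.sex_probability_female <= 1:
            raise ValueError("sex_probability_female must be a probability")
        if self.sensitivity_range != (0.0, 36.0):
            raise ValueError("sensitivity_range is fixed to the instrument's 36 dB")
        if self.rezr_effect_level not in ("point", "participant_mean", "global"):
            raise ValueError("rezr_effect_level must be point|participant_mean|global")
        for v in (
            self.intercept,
            self.effect_beta_rezr,
            self.effect_beta_age,
            self.effect_beta_male,
            *self.stage_offsets.values(),
        ):
            if not np.isfinite(v):
                raise ValueError("linear predictor coefficients must be finite")


@dataclass
class CohortTable:
    """One record per participant-eye plus a 33-row point table per eye."""

    participants: pd.DataFrame
    points: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.points.groupby("id").size()
        if not (counts == 33).all():
            raise ValueError("every eye must carry exactly 33 point records")
        s = self.points["sensitivity_db"]
        if (s < 0).any() or (s > 36).any():
            raise ValueError("sensitivities must lie in [0, 36] dB")

    def points_with_covariates(self) -> pd.DataFrame:
        cov = self.participants[["id", "age", "sex", "stage"]]
        return self.points.merge(cov, on="id", validate="many_to_one")


def simulate_cohort(
    config: CohortConfig,
    rezr_fields: Sequence[np.ndarray | float] | None = None,
    stages: Sequence[str] | None = None,
) -> CohortTable:
    """Simulate a cohort of participant-eyes with 33-point functional data.

    ``rezr_fields`` optionally fixes the local rEZR values: one entry per
    participant, either a length-33 array (values at the stimulus points) or
    a scalar (uniform field).  Without it, fields are drawn parametrically:
    a stage-dependent participant mean, a linear eccentricity trend and
    point-level scatter.  ``stages`` optionally fixes the per-participant
    stage labels (otherwise drawn from ``stage_probabilities``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    grid = make_grid()
    ecc = grid.points["eccentricity_deg"].to_numpy()
    mean_ecc = ecc.mean()

    if stages is None:
        labels = list(config.stage_probabilities)
        probs = [config.stage_probabilities[s] for s in labels]
        stages = rng.choice(labels, size=n, p=probs)
    else:
        stages = np.asarray(stages, dtype=object)
        if len(stages) != n:
            raise ValueError("stages must have one entry per participant")
    if rezr_fields is not None and len(rezr_fields) != n:
        raise ValueError("need one rEZR field per participant")

    age = np.clip(
        rng.normal(config.age_distribution[0], config.age_distribution[1], n), 50, 95
    )
    female = rng.random(n) < config.sex_probability_female

    part_rows = []
    point_rows = []
    for i in range(n):
        stage = stages[i]
        m, sd = config.rezr_stage_params[stage]
        mean_i = max(rng.normal(m, sd), 1.0)
        if rezr_fields is not None:
            f = rezr_fields[i]
            local = np.full(33, float(f)) if np.isscalar(f) else np.asarray(f, dtype=float)
            if local.shape != (33,):
                raise ValueError("per-participant rEZR field must have 33 values")
            global_rezr = float(local.mean())
        else:
            local = (
                mean_i
                + config.rezr_ecc_slope * (ecc - mean_ecc)
                + rng.normal(0.0, config.rezr_point_sd, 33)
            )
            local = np.clip(local, 0.1, None)
            global_rezr = mean_i
        central = float(local[np.argmin(ecc)])

        if config.rezr_effect_level == "point":
            x = local
        elif config.rezr_effect_level == "participant_mean":
            x = np.full(33, local.mean())
        else:
            x = np.full(33, global_rezr)

        fixed = (
            config.intercept
            + config.effect_beta_rezr * x
            + config.effect_beta_age * age[i]
            + (0.0 if female[i] else config.effect_beta_male)
            + config.stage_offsets[stage]
            - config.ecc_dip_db * np.exp(-((ecc / config.ecc_dip_scale_deg) ** 2))
        )
        if not np.all(np.isfinite(fixed)):
            raise ValueError("non-finite linear predictor")
        u = rng.normal(0.0, config.random_intercept_sd) if config.random_intercept_sd else 0.0
        e = rng.normal(0.0, config.residual_sd, 33) if config.residual_sd else 0.0
        sens = np.clip(fixed + u + e, *config.sensitivity_range)

        charts = {}
        for name, (b0, br, soff, bage, bmale, csd) in config.chart_models.items():
            mu = (
                b0
                + br * global_rezr
                + dict(zip(STAGES, soff))[stage]
                + bage * age[i]
                + (0.0 if female[i] else bmale)
            )
            charts[name] = mu + (rng.normal(0.0, csd) if csd else 0.0)
        lld = derive_lld(charts["bcva"], charts["llva"], convention=config.lld_convention)

        pid = f"P{i:04d}"
        part_rows.append(
            {
                "id": pid,
                "age": age[i],
                "sex": "female" if female[i] else "male",
                "stage": stage,
                "global_rezr": global_rezr,
                "central_subfield_rezr": central,
                "mesat_db": float(sens.mean()),
                "bcva": charts["bcva"],
                "llva": charts["llva"],
                "mat": charts["mat"],
                "pr": charts["pr"],
                "lld": lld,
            }
        )
        for p in range(33):
            point_rows.append(
                {
                    "id": pid,
                    "point_id": int(grid.points["point_id"].iloc[p]),
                    "eccentricity_deg": float(ecc[p]),
                    "azimuth_deg": float(grid.points["azimuth_deg"].iloc[p]),
                    "local_rezr": float(local[p]),
                    "sensitivity_db": float(sens[p]),
                }
            )
    return CohortTable(
        participants=pd.DataFrame(part_rows), points=pd.DataFrame(point_rows)
    )
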