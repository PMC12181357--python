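"""Relative ellipsoid zone reflectivity (rEZR) quantification.

The rEZR is the ratio of the peak reflectivity of the ellipsoid zone (EZ) to
the peak reflectivity of the external limiting membrane (ELM), computed on
raw linear-intensity OCT A-scans (dynamic range 0..1 AU).  Because both
peaks share acquisition gain, the ratio cancels per-scan illumination
differences.

The processing chain per B-scan:

1. :func:`flatten` — straighten the B-scan along the retinal pigment
   epithelium (RPE) using integer column shifts (raw intensities are never
   interpolated).
2. :func:`build_profiles` — average adjoining 9-pixel windows along the
   lateral axis into axial reflectivity profiles.
3. :func:`calibrate_windows` — derive EZ/ELM peak-search windows from the
   95% prediction interval of reference peak offsets.
4. :func:`find_peaks_profile` — locate the EZ and ELM peaks inside their
   windows (local maxima with a noise-scaled prominence requirement).
5. :func:`compute_rezr` — form the EZ/ELM ratio.

Exclusion masks remove regions with sub-RPE drusen (RPE-to-Bruch's-membrane
separation strictly greater than 15 px, about 100 um), regions where either
peak is absent (atrophy / neovascularization), and regions without valid
segmentation.  :func:`compute_map` ties everything into an en-face
:class:`REZRMap`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.signal
import scipy.stats

LAYER_NAMES = ("ILM", "ELM", "EZ", "RPE", "BM")

#: default visual-angle to retinal-distance conversion, um per degree
DEGREES_TO_UM = 288.0

#: default lateral sampling of a 30 deg / 768 px raster, um per pixel
LATERAL_SCALE_UM = DEGREES_TO_UM * 30.0 / 768.0

#: default axial sampling (high-speed Spectralis-like), um per pixel
AXIAL_SCALE_UM = 3.87


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OCTVolume:
    """A raster OCT volume of linear-intensity A-scans.

    Parameters
    ----------
    intensities
        Array of shape ``(n_bscans, n_rows, n_ascans)`` with values in
        ``[0, 1]`` AU.  Row index increases with depth.
    axial_scale, lateral_scale, bscan_spacing
        Physical sampling in micrometres per pixel / per B-scan.
    fovea_center
        ``(bscan, ascan)`` index of the foveal center; defaults to the
        volume center.
    """

    intensities: np.ndarray
    axial_scale: float = AXIAL_SCALE_UM
    lateral_scale: float = LATERAL_SCALE_UM
    bscan_spacing: float = 30.0
    fovea_center: tuple[int, int] | None = None
    # set by flatten()
    flatten_shifts: np.ndarray | None = None
    target_rpe_row: int | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (bscan, row, ascan)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        lo, hi = self.intensities.min(), self.intensities.max()
        if lo < -1e-9 or hi > 1.0 + 1e-9:
            raise ValueError(f"intensities outside [0, 1] AU (min {lo}, max {hi})")
        for name in ("axial_scale", "lateral_scale", "bscan_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fovea_center is None:
            self.fovea_center = (self.n_bscans // 2, self.n_ascans // 2)

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_ascans(self) -> int:
        return self.intensities.shape[2]


@dataclass
class SegmentationSurfaces:
    """Per-A-scan row coordinates of the retinal surfaces.

    ``rows`` maps each of ILM, ELM, EZ, RPE, BM to a ``(n_bscans, n_ascans)``
    float array of row indices; NaN marks missing segmentation.  Where all
    layers are present the depth ordering ``BM >= RPE >= EZ >= ELM >= ILM``
    must hold (rows grow with depth).
    """

    rows: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(LAYER_NAMES) - set(self.rows)
        if missing:
            raise ValueError(f"missing surfaces: {sorted(missing)}")
        shape = None
        for name in LAYER_NAMES:
            arr = np.asarray(self.rows[name], dtype=float)
            self.rows[name] = arr
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("all surfaces must share one (bscan, ascan) shape")
        present = ~self.any_missing()
        order = ("BM", "RPE", "EZ", "ELM", "ILM")
        for upper, lower in zip(order[:-1], order[1:]):
            a, b = self.rows[upper], self.rows[lower]
            viol = present & (a < b)
            if np.any(viol):
                raise ValueError(f"surface ordering violated: {upper} above {lower}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rows["RPE"].shape

    def layer(self, name: str) -> np.ndarray:
        return self.rows[name]

    def any_missing(self) -> np.ndarray:
        """Boolean (bscan, ascan) mask: any surface missing in that column."""
        out = np.zeros(self.rows["RPE"].shape, dtype=bool)
        for name in LAYER_NAMES:
            out |= ~np.isfinite(self.rows[name])
        return out

    def shifted(self, shifts: np.ndarray) -> "SegmentationSurfaces":
        return SegmentationSurfaces(
            rows={k: v - shifts for k, v in self.rows.items()}
        )


@dataclass
class ReflectivityProfile:
    """Mean axial reflectivity over one 9-column region of interest."""

    roi_id: tuple[int, int]
    values: np.ndarray  # mean linear intensity by (flattened) row
    window_columns: tuple[int, int]  # half-open [start, stop)
    rpe_row: int
    ilm_row: float  # mean shifted ILM row (NaN if unknown)
    no_segmentation: bool = False
    partial: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("profile values must be non-negative")


@dataclass(frozen=True)
class PeakWindows:
    """Peak-search windows in pixels above the flattened RPE row."""

    ez_window: tuple[int, int]
    elm_window: tuple[int, int]
    level: float = 0.95

    def __post_init__(self) -> None:
        for w in (self.ez_window, self.elm_window):
            if w[1] < w[0]:
                raise ValueError(f"empty window {w}")
        if self.elm_window[0] <= self.ez_window[1]:
            raise ValueError("ELM window must lie strictly above the EZ window")


@dataclass
class PeakResult:
    roi_id: tuple[int, int]
    ez_peak: float = np.nan
    ez_offset: float = np.nan
    elm_peak: float = np.nan
    elm_offset: float = np.nan
    ez_present: bool = False
    elm_present: bool = False


@dataclass
class ExclusionMask:
    """Boolean en-face exclusion flags at ROI resolution, by cause."""

    kind: str
    flags: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("drusen", "atrophy", "no_segmentation", "edge"):
            raise ValueError(f"unknown exclusion kind {self.kind!r}")
        self.flags = np.asarray(self.flags, dtype=bool)


@dataclass
class REZRMap:
    """En-face map of rEZR values at ROI resolution with exclusions.

    ``values`` has shape ``(n_bscans, n_rois)``; excluded cells are NaN.
    Geometry is given as ROI-center coordinates relative to the fovea in
    micrometres and degrees of visual angle.
    """

    values: np.ndarray
    exclusions: dict[str, np.ndarray]
    x_um: np.ndarray  # (n_rois,)
    y_um: np.ndarray  # (n_bscans,)
    degrees_to_um: float = DEGREES_TO_UM
    fovea_center: tuple[int, int] = (0, 0)
    window: int = 9

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_deg(self) -> np.ndarray:
        return self.x_um / self.degrees_to_um

    @property
    def y_deg(self) -> np.ndarray:
        return self.y_um / self.degrees_to_um

    @property
    def combined_exclusions(self) -> np.ndarray:
        out = np.zeros(self.values.shape, dtype=bool)
        for flags in self.exclusions.values():
            out |= flags
        return out

    @property
    def included(self) -> np.ndarray:
        return ~self.combined_exclusions & np.isfinite(self.values)

    def global_mean(self) -> float:
        inc = self.included
        if not inc.any():
            raise ValueError("no included ROIs")
        return float(self.values[inc].mean())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def flatten(
    volume: OCTVolume,
    surfaces: SegmentationSurfaces,
    target_row: int | None = None,
) -> tuple[OCTVolume, SegmentationSurfaces]:
    """Straighten each B-scan along the RPE by integer column shifts.

    Every column with a valid RPE row is shifted so the RPE lands on
    ``target_row`` (default: the rounded median RPE row of the volume).
    Shifted-out rows are zero padded; intensities are never interpolated.
    Columns with missing RPE are left unshifted (they are excluded later as
    ``no_segmentation``).  All surfaces are shifted by the same offsets.
    """
    rpe = surfaces.layer("RPE")
    if rpe.shape != (volume.n_bscans, volume.n_ascans):
        raise ValueError("surface shape does not match volume")
    valid = np.isfinite(rpe)
    if target_row is None:
        if not valid.any():
            raise ValueError("no valid RPE rows to flatten against")
        target_row = int(round(float(np.nanmedian(rpe))))
    shifts = np.zeros(rpe.shape, dtype=int)
    shifts[valid] = np.round(rpe[valid]).astype(int) - target_row

    n_rows = volume.n_rows
    rows = np.arange(n_rows)
    # out[b, r, x] = in[b, r + shift[b, x], x]  (zero outside)
    src = rows[None, :, None] + shifts[:, None, :]
    inside = (src >= 0) & (src < n_rows)
    flat = np.where(
        inside,
        np.take_along_axis(volume.intensities, np.clip(src, 0, n_rows - 1), axis=1),
        0.0,
    )
    out = OCTVolume(
        intensities=flat,
        axial_scale=volume.axial_scale,
        lateral_scale=volume.lateral_scale,
        bscan_spacing=volume.bscan_spacing,
        fovea_center=volume.fovea_center,
    )
    out.flatten_shifts = shifts
    out.target_rpe_row = target_row
    shifted = surfaces.shifted(shifts.astype(float))
    return out, shifted


def build_profiles(
    flat_volume: OCTVolume,
    shifted_surfaces: SegmentationSurfaces,
    bscan: int,
    window: int = 9,
    include_partial: bool = False,
) -> list[ReflectivityProfile]:
    """Average adjoining ``window``-column intervals into axial profiles.

    One profile is produced per full non-overlapping window; a narrower
    terminal remainder is flagged ``partial`` and only returned when
    ``include_partial`` is set.  Profiles whose window contains any column
    with missing segmentation are flagged ``no_segmentation``.
    """
    if flat_volume.target_rpe_row is None:
        raise ValueError("volume must be flattened first")
    img = flat_volume.intensities[bscan]
    n_ascans = img.shape[1]
    missing = shifted_surfaces.any_missing()[bscan]
    ilm = shifted_surfaces.layer("ILM")[bscan]
    profiles: list[ReflectivityProfile] = []
    n_full = n_ascans // window
    bounds = [(i * window, (i + 1) * window) for i in range(n_full)]
    if include_partial and n_full * window < n_ascans:
        bounds.append((n_full * window, n_ascans))
    for i, (start, stop) in enumerate(bounds):
        block = img[:, start:stop]
        with np.errstate(invalid="ignore"):
            ilm_row = float(np.nanmean(ilm[start:stop]))
        profiles.append(
            ReflectivityProfile(
                roi_id=(bscan, i),
                values=block.mean(axis=1),
                window_columns=(start, stop),
                rpe_row=flat_volume.target_rpe_row,
                ilm_row=ilm_row,
                no_segmentation=bool(missing[start:stop].any()),
                partial=(stop - start) < window,
            )
        )
    return profiles


#: broad anatomical search bands, px above the flattened RPE, used when
#: calibrating the prediction-interval windows
DEFAULT_EZ_BAND = (2, 10)
DEFAULT_ELM_BAND = (11, 22)


def _band_argmax(profile: ReflectivityProfile, band: tuple[int, int]) -> tuple[int, float]:
    """Offset (px above RPE) and value of the maximum within a band."""
    r0 = profile.rpe_row
    lo_row = max(r0 - band[1], 0)
    hi_row = min(r0 - band[0], len(profile.values) - 1)
    if hi_row < lo_row:
        raise ValueError("band outside profile")
    seg = profile.values[lo_row : hi_row + 1]
    idx = int(np.argmax(seg))
    row = lo_row + idx
    return r0 - row, float(seg[idx])


def calibrate_windows(
    reference_profiles: Sequence[ReflectivityProfile],
    level: float = 0.95,
    ez_band: tuple[int, int] = DEFAULT_EZ_BAND,
    elm_band: tuple[int, int] = DEFAULT_ELM_BAND,
) -> PeakWindows:
    """Derive EZ/ELM peak windows from reference peak offsets.

    For each reference profile the argmax offset inside a broad anatomical
    band is recorded; the window is the two-sided normal-theory prediction
    interval ``mean +/- t * sd * sqrt(1 + 1/n)`` of those offsets at the
    requested coverage, rounded outward to whole pixels and clipped to the
    band.  At least 10 reference profiles are required.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if elm_band[0] <= ez_band[1]:
        raise ValueError("ez_band and elm_band must be disjoint, ELM above EZ")
    refs = [p for p in reference_profiles if not (p.no_segmentation or p.partial)]
    if len(refs) < 10:
        raise ValueError(f"need >= 10 reference profiles, got {len(refs)}")

    def interval(band: tuple[int, int]) -> tuple[int, int]:
        offsets = np.array([_band_argmax(p, band)[0] for p in refs], dtype=float)
        n = len(offsets)
        m = offsets.mean()
        sd = offsets.std(ddof=1)
        t = scipy.stats.t.ppf(0.5 + level / 2.0, n - 1)
        half = t * sd * math.sqrt(1.0 + 1.0 / n)
        lo = int(math.floor(m - half))
        hi = int(math.ceil(m + half))
        return max(lo, band[0]), min(hi, band[1])

    return PeakWindows(ez_window=interval(ez_band), elm_window=interval(elm_band), level=level)


def estimate_noise(profile: ReflectivityProfile, margin: int = 4) -> float:
    """Noise sd estimated from the vitreous band above the ILM."""
    if not np.isfinite(profile.ilm_row):
        return 0.0
    stop = int(profile.ilm_row) - margin
    if stop < 5:
        return 0.0
    return float(profile.values[:stop].std(ddof=0))


def find_peaks_profile(
    profile: ReflectivityProfile,
    windows: PeakWindows,
    k: float = 2.0,
    prominence_floor: float = 1e-6,
) -> PeakResult:
    """Locate the EZ and ELM peaks within their calibrated windows.

    A peak is the largest local maximum inside the window whose prominence
    is at least ``max(k * noise, prominence_floor)``, with noise estimated
    from the vitreous.  Ties are broken toward the smaller offset (closer to
    the RPE).  A window without a qualifying local maximum yields an absent
    flag — never a value.
    """
    res = PeakResult(roi_id=profile.roi_id)
    values = profile.values
    thr = max(k * estimate_noise(profile), prominence_floor)
    candidates, _ = scipy.signal.find_peaks(values, prominence=thr)

    def pick(window: tuple[int, int]) -> tuple[float, float, bool]:
        r0 = profile.rpe_row
        lo_row, hi_row = r0 - window[1], r0 - window[0]
        if lo_row < 0 or hi_row >= len(values):
            return np.nan, np.nan, False
        cand = candidates[(candidates >= lo_row) & (candidates <= hi_row)]
        if cand.size == 0:
            return np.nan, np.nan, False
        best = values[cand].max()
        ties = cand[values[cand] >= best - 1e-12]
        row = int(ties.max())  # largest row == smallest offset above RPE
        while row + 1 <= hi_row and values[row + 1] >= values[row] - 1e-12:
            row += 1  # walk a flat plateau toward the RPE
        return float(values[row]), float(r0 - row), True

    res.ez_peak, res.ez_offset, res.ez_present = pick(windows.ez_window)
    res.elm_peak, res.elm_offset, res.elm_present = pick(windows.elm_window)
    return res


def compute_rezr(
    peaks: PeakResult,
    elm_floor: float = 1e-6,
    scale_factor: float = 1.0,
) -> float | None:
    """EZ/ELM peak ratio in AU, or ``None`` when undefined.

    Returns ``None`` (excluded) when either peak is absent or the ELM peak
    falls below the positivity floor — never infinity.
    """
    if not (peaks.ez_present and peaks.elm_present):
        return None
    if peaks.elm_peak < elm_floor:
        return None
    return scale_factor * peaks.ez_peak / peaks.elm_peak


def mask_drusen(
    surfaces: SegmentationSurfaces,
    threshold_px: float = 15,
    window: int = 9,
) -> ExclusionMask:
    """Sub-RPE drusen exclusion at ROI resolution.

    An ROI is excluded iff any of its columns has an RPE-to-Bruch's-membrane
    separation strictly greater than ``threshold_px`` (~100 um at 15 px).
    Columns with missing RPE or BM contribute nothing here (they are handled
    by the ``no_segmentation`` mask).
    """
    sep = surfaces.layer("BM") - surfaces.layer("RPE")
    n_bscans, n_ascans = sep.shape
    n_rois = n_ascans // window
    flags = np.zeros((n_bscans, n_rois), dtype=bool)
    over = np.isfinite(sep) & (sep > threshold_px)
    for i in range(n_rois):
        flags[:, i] = over[:, i * window : (i + 1) * window].any(axis=1)
    return ExclusionMask(kind="drusen", flags=flags)


def mask_atrophy(peaks: Sequence[Sequence[PeakResult]]) -> ExclusionMask:
    """Exclude ROIs where the EZ or ELM peak is absent (GA / MNV surrogate)."""
    flags = np.array(
        [[not (p.ez_present and p.elm_present) for p in row] for row in peaks],
        dtype=bool,
    )
    return ExclusionMask(kind="atrophy", flags=flags)


def compute_map(
    volume: OCTVolume,
    surfaces: SegmentationSurfaces,
    windows: PeakWindows | None = None,
    window: int = 9,
    threshold_px: float = 15,
    k: float = 2.0,
    pi_level: float = 0.95,
    ez_band: tuple[int, int] = DEFAULT_EZ_BAND,
    elm_band: tuple[int, int] = DEFAULT_ELM_BAND,
    scale_factor: float = 1.0,
    degrees_to_um: float = DEGREES_TO_UM,
    calibration_amp_floor: float = 0.01,
) -> REZRMap:
    """Run the full quantification chain and return the en-face rEZR map.

    When ``windows`` is None they are calibrated from this volume's own
    profiles, using as reference the profiles whose band maxima both exceed
    ``calibration_amp_floor`` AU (a proxy for control-like regions with both
    peaks clearly present).
    """
    flat, shifted = flatten(volume, surfaces)
    all_profiles: list[list[ReflectivityProfile]] = [
        build_profiles(flat, shifted, b, window=window)
        for b in range(volume.n_bscans)
    ]
    if windows is None:
        refs = []
        for row in all_profiles:
            for p in row:
                if p.no_segmentation:
                    continue
                try:
                    ez_v = _band_argmax(p, ez_band)[1]
                    elm_v = _band_argmax(p, elm_band)[1]
                except ValueError:
                    continue
                if ez_v > calibration_amp_floor and elm_v > calibration_amp_floor:
                    refs.append(p)
        windows = calibrate_windows(refs, level=pi_level, ez_band=ez_band, elm_band=elm_band)

    peaks = [
        [find_peaks_profile(p, windows, k=k) for p in row] for row in all_profiles
    ]
    n_rois = volume.n_ascans // window
    values = np.full((volume.n_bscans, n_rois), np.nan)
    for b, row in enumerate(peaks):
        for i, pk in enumerate(row):
            r = compute_rezr(pk, scale_factor=scale_factor)
            if r is not None:
                values[b, i] = r

    drusen = mask_drusen(surfaces, threshold_px=threshold_px, window=window)
    atrophy = mask_atrophy(peaks)
    no_seg = np.array(
        [[p.no_segmentation for p in row] for row in all_profiles], dtype=bool
    )
    edge = np.zeros_like(no_seg)  # terminal partial ROIs never enter the grid
    values[drusen.flags | atrophy.flags | no_seg] = np.nan

    fb, fa = volume.fovea_center
    centers = np.arange(n_rois) * window + (window - 1) / 2.0
    x_um = (centers - fa) * volume.lateral_scale
    y_um = (np.arange(volume.n_bscans) - fb) * volume.bscan_spacing
    return REZRMap(
        values=values,
        exclusions={
            "drusen": drusen.flags,
            "atrophy": atrophy.flags,
            "no_segmentation": no_seg,
            "edge": edge,
        },
        x_um=x_um,
        y_um=y_um,
        degrees_to_um=degrees_to_um,
        fovea_center=volume.fovea_center,
        window=window,
    )
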