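"""Quantification chain: flattening, profiles, peak windows, masks, map."""

import numpy as np
import pytest
import scipy.stats

from ezreflect import quantify
from ezreflect.phantom import PhantomParams, generate_volume
from ezreflect.quantify import (
    OCTVolume,
    PeakResult,
    PeakWindows,
    ReflectivityProfile,
    SegmentationSurfaces,
    build_profiles,
    calibrate_windows,
    compute_map,
    compute_rezr,
    find_peaks_profile,
    flatten,
    mask_atrophy,
    mask_drusen,
)


def make_surfaces(rpe, offsets=dict(BM=-10, EZ=7, ELM=14, ILM=90)):
    rpe = np.asarray(rpe, dtype=float)
    return SegmentationSurfaces(
        rows={
            "RPE": rpe.copy(),
            "BM": rpe - offsets["BM"],
            "EZ": rpe - offsets["EZ"],
            "ELM": rpe - offsets["ELM"],
            "ILM": rpe - offsets["ILM"],
        }
    )


def gaussian_profile(rpe_row, n_rows, peaks, ilm_offset=90):
    """Synthetic profile from (offset_above_rpe, amplitude, width) peaks."""
    r = np.arange(n_rows, dtype=float)
    v = np.zeros(n_rows)
    for off, amp, w in peaks:
        v += amp * np.exp(-((r - (rpe_row - off)) ** 2) / (2 * w**2))
    return ReflectivityProfile(
        roi_id=(0, 0),
        values=v,
        window_columns=(0, 9),
        rpe_row=rpe_row,
        ilm_row=rpe_row - ilm_offset,
    )


WINDOWS = PeakWindows(ez_window=(4, 10), elm_window=(11, 18))


class TestFlatten:
    def test_already_flat_is_identity(self, flat_phantom):
        volume, truth = flat_phantom
        flat, shifted = flatten(volume, truth.surfaces)
        assert np.all(flat.flatten_shifts == 0)
        assert np.array_equal(flat.intensities, volume.intensities)

    def test_tilted_rpe_shift_oracle(self):
        n_rows, n_cols = 140, 60
        rpe = 60 + np.round(np.linspace(0, 30, n_cols))[None, :]
        surf = make_surfaces(rpe)
        img = np.zeros((1, n_rows, n_cols))
        img[0, rpe[0].astype(int), np.arange(n_cols)] = 1.0
        vol = OCTVolume(img)
        flat, shifted = flatten(vol, surf)
        target = flat.target_rpe_row
        assert np.array_equal(flat.flatten_shifts[0], rpe[0].astype(int) - target)
        # post-flattening the RPE row is constant (variance 0)
        assert np.ptp(shifted.layer("RPE")) == 0
        assert np.all(flat.intensities[0, target, :] == 1.0)

    def test_zero_image_stays_zero(self):
        rpe = 60 + np.round(np.linspace(0, 20, 30))[None, :]
        vol = OCTVolume(np.zeros((1, 120, 30)))
        flat, _ = flatten(vol, make_surfaces(rpe))
        assert not flat.intensities.any()

    def test_missing_rpe_column_left_unshifted(self):
        rpe = np.full((1, 30), 70.0)
        rpe[0, 5] = np.nan
        surf = make_surfaces(rpe)
        vol = OCTVolume(np.zeros((1, 120, 30)))
        flat, _ = flatten(vol, surf, target_row=60)
        assert flat.flatten_shifts[0, 5] == 0
        assert np.all(flat.flatten_shifts[0, :5] == 10)


class TestBuildProfiles:
    def make_flat(self, n_cols, value=0.25):
        rpe = np.full((1, n_cols), 70.0)
        vol = OCTVolume(np.full((1, 120, n_cols), value))
        return flatten(vol, make_surfaces(rpe))

    def test_768_columns_split_into_85_full_rois(self):
        flat, shifted = self.make_flat(768)
        full = build_profiles(flat, shifted, 0)
        assert len(full) == 85
        both = build_profiles(flat, shifted, 0, include_partial=True)
        assert len(both) == 86
        assert both[-1].partial and both[-1].window_columns == (765, 768)
        assert all(not p.partial for p in full)

    def test_constant_image_gives_constant_profiles(self):
        flat, shifted = self.make_flat(45, value=0.3)
        for p in build_profiles(flat, shifted, 0):
            assert np.allclose(p.values, 0.3)

    def test_noise_free_phantom_profile_equals_template(self, flat_phantom):
        volume, truth = flat_phantom
        flat, shifted = flatten(volume, truth.surfaces)
        profiles = build_profiles(flat, shifted, 0)
        # all columns identical, so the window mean is the single A-scan
        assert np.allclose(profiles[0].values, volume.intensities[0, :, 0])

    def test_missing_segmentation_flagged(self):
        rpe = np.full((1, 27), 70.0)
        surf = make_surfaces(rpe)
        surf.rows["EZ"][0, 10] = np.nan
        vol = OCTVolume(np.zeros((1, 120, 27)))
        flat, shifted = flatten(vol, surf)
        flags = [p.no_segmentation for p in build_profiles(flat, shifted, 0)]
        assert flags == [False, True, False]


class TestCalibrateWindows:
    def refs(self, offsets_ez, offsets_elm, rpe_row=80, n_rows=140):
        return [
            gaussian_profile(rpe_row, n_rows, [(oe, 0.7, 1.0), (om, 0.3, 1.0)])
            for oe, om in zip(offsets_ez, offsets_elm)
        ]

    def test_zero_variance_collapses_to_offset(self):
        profiles = self.refs([7] * 12, [14] * 12)
        w = calibrate_windows(profiles)
        assert w.ez_window == (7, 7)
        assert w.elm_window == (14, 14)

    def test_level_nesting(self):
        rng = np.random.default_rng(0)
        ez = np.clip(np.round(rng.normal(7, 1.2, 40)), 3, 9).astype(int)
        elm = np.clip(np.round(rng.normal(15, 1.2, 40)), 12, 20).astype(int)
        profiles = self.refs(ez, elm)
        w50 = calibrate_windows(profiles, level=0.5)
        w95 = calibrate_windows(profiles, level=0.95)
        assert w95.ez_window[0] <= w50.ez_window[0] <= w50.ez_window[1] <= w95.ez_window[1]
        assert w95.elm_window[0] <= w50.elm_window[0] <= w50.elm_window[1] <= w95.elm_window[1]

    def test_too_few_references_refused(self):
        with pytest.raises(ValueError, match=">= 10"):
            calibrate_windows(self.refs([7] * 9, [14] * 9))

    def test_monte_carlo_coverage(self):
        rng = np.random.default_rng(1)

        def draw(n):
            ez = np.clip(np.round(rng.normal(6.5, 1.0, n)), 3, 9).astype(int)
            elm = np.clip(np.round(rng.normal(15.0, 1.3, n)), 12, 20).astype(int)
            return ez, elm

        ez, elm = draw(400)
        w = calibrate_windows(self.refs(ez, elm))
        ez_h, elm_h = draw(2000)
        cov_ez = np.mean((ez_h >= w.ez_window[0]) & (ez_h <= w.ez_window[1]))
        cov_elm = np.mean((elm_h >= w.elm_window[0]) & (elm_h <= w.elm_window[1]))
        assert cov_ez >= 0.95
        assert cov_elm >= 0.95


class TestFindPeaks:
    def test_clean_peaks_match_bruteforce_argmax(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            # keep the peaks >= 4 px apart, as real EZ/ELM bands are
            oe = int(rng.integers(WINDOWS.ez_window[0], 9))
            om = int(rng.integers(13, WINDOWS.elm_window[1] + 1))
            ae, am = rng.uniform(0.3, 0.9), rng.uniform(0.05, 0.25)
            p = gaussian_profile(80, 140, [(oe, ae, 1.0), (om, am, 1.0), (0, 0.9, 1.0)])
            res = find_peaks_profile(p, WINDOWS)
            assert res.ez_present and res.elm_present
            assert res.ez_offset == oe and res.elm_offset == om
            # brute-force: argmax over the window rows
            rows = np.arange(80 - WINDOWS.ez_window[1], 80 - WINDOWS.ez_window[0] + 1)
            assert res.ez_peak == p.values[rows].max()

    def test_flat_profile_has_no_peaks(self):
        p = ReflectivityProfile((0, 0), np.full(140, 0.2), (0, 9), rpe_row=80, ilm_row=10.0)
        res = find_peaks_profile(p, WINDOWS)
        assert not res.ez_present and not res.elm_present

    def test_atrophic_profile_flags_absent(self):
        p = gaussian_profile(80, 140, [(0, 0.9, 1.0), (-10, 0.35, 1.0)])
        res = find_peaks_profile(p, WINDOWS)
        assert not res.ez_present and not res.elm_present

    def test_short_profile_flagged_absent(self):
        p = ReflectivityProfile((0, 0), np.full(15, 0.1), (0, 9), rpe_row=80, ilm_row=np.nan)
        res = find_peaks_profile(p, WINDOWS)
        assert not res.ez_present and not res.elm_present

    def test_plateau_tie_breaks_toward_rpe(self):
        v = np.zeros(140)
        v[80 - 8 : 80 - 5] = 0.5  # flat plateau spanning offsets 6..8
        p = ReflectivityProfile((0, 0), v, (0, 9), rpe_row=80, ilm_row=5.0)
        res = find_peaks_profile(p, WINDOWS)
        assert res.ez_present and res.ez_offset == 6


class TestComputeRezr:
    def test_ratio_arithmetic(self):
        pk = PeakResult((0, 0), ez_peak=0.5, elm_peak=0.01, ez_present=True, elm_present=True)
        assert compute_rezr(pk) == pytest.approx(50.0)
        pk2 = PeakResult((0, 0), ez_peak=0.2, elm_peak=0.2, ez_present=True, elm_present=True)
        assert compute_rezr(pk2) == pytest.approx(1.0)

    def test_degenerate_inputs_excluded(self):
        assert compute_rezr(PeakResult((0, 0))) is None
        pk = PeakResult((0, 0), ez_peak=0.5, elm_peak=0.0, ez_present=True, elm_present=True)
        assert compute_rezr(pk) is None


class TestMasks:
    def test_separation_threshold_is_strict(self):
        for sep, expected in [(16.0, True), (15.0, False), (10.0, False)]:
            rpe = np.full((1, 18), 70.0)
            surf = make_surfaces(rpe, offsets=dict(BM=-sep, EZ=7, ELM=14, ILM=90))
            m = mask_drusen(surf, threshold_px=15)
            assert m.flags.all() == expected

    def test_missing_bm_is_not_drusen(self):
        rpe = np.full((1, 9), 70.0)
        surf = make_surfaces(rpe, offsets=dict(BM=-20, EZ=7, ELM=14, ILM=90))
        surf.rows["BM"][:] = np.nan
        assert not mask_drusen(surf).flags.any()

    def test_threshold_monotonicity(self, pathology_phantom):
        _, truth = pathology_phantom
        m_low = mask_drusen(truth.surfaces, threshold_px=10).flags
        m_mid = mask_drusen(truth.surfaces, threshold_px=15).flags
        assert np.all(m_mid <= m_low)

    def test_phantom_druse_matches_truth_at_roi_resolution(self, pathology_phantom):
        _, truth = pathology_phantom
        flags = mask_drusen(truth.surfaces, threshold_px=15, window=9).flags
        expected = np.array(
            [
                truth.drusen_mask_truth[:, i * 9 : (i + 1) * 9].any(axis=1)
                for i in range(truth.drusen_mask_truth.shape[1] // 9)
            ]
        ).T
        assert np.array_equal(flags, expected)

    def test_atrophy_mask_either_peak_rule(self):
        present = PeakResult((0, 0), ez_present=True, elm_present=True)
        no_elm = PeakResult((0, 1), ez_present=True, elm_present=False)
        m = mask_atrophy([[present, no_elm]])
        assert m.flags.tolist() == [[False, True]]


class TestComputeMap:
    def test_noise_free_phantom_matches_truth(self, pathology_phantom):
        volume, truth = pathology_phantom
        m = compute_map(volume, truth.surfaces)
        inc = m.included
        assert inc.any()
        rel = np.abs(m.values[inc] - 37.0) / 37.0
        assert rel.max() < 1e-6

    def test_atrophy_exclusion_covers_truth(self, pathology_phantom):
        volume, truth = pathology_phantom
        m = compute_map(volume, truth.surfaces)
        n_rois = m.shape[1]
        truth_roi = np.array(
            [
                truth.atrophy_mask_truth[:, i * 9 : (i + 1) * 9].any(axis=1)
                for i in range(n_rois)
            ]
        ).T
        # every truly atrophic ROI is excluded (1-ROI boundary tolerance)
        core = np.array(
            [
                truth.atrophy_mask_truth[:, i * 9 : (i + 1) * 9].all(axis=1)
                for i in range(n_rois)
            ]
        ).T
        assert np.all(m.exclusions["atrophy"][core])
        assert np.all(~m.included[truth_roi & core])

    def test_gain_invariance_single_field(self, pathology_phantom):
        volume, truth = pathology_phantom
        base = compute_map(volume, truth.surfaces)
        rng = np.random.default_rng(3)
        gains = rng.uniform(0.3, 1.1, volume.n_bscans)
        gained = quantify.OCTVolume(
            volume.intensities * gains[:, None, None],
            fovea_center=volume.fovea_center,
        )
        m2 = compute_map(gained, truth.surfaces)
        assert np.array_equal(base.included, m2.included)
        inc = base.included
        rel = np.abs(m2.values[inc] - base.values[inc]) / base.values[inc]
        assert rel.max() < 1e-9

    def test_empty_map_mean_raises(self, flat_phantom):
        volume, truth = flat_phantom
        m = compute_map(volume, truth.surfaces)
        m.exclusions["no_segmentation"][:] = True
        with pytest.raises(ValueError, match="no included ROIs"):
            m.global_mean()

    def test_fovea_shift_moves_geometry_not_values(self, flat_phantom):
        volume, truth = flat_phantom
        m1 = compute_map(volume, truth.surfaces)
        shifted = quantify.OCTVolume(
            volume.intensities, fovea_center=(volume.fovea_center[0], volume.fovea_center[1] + 9)
        )
        m2 = compute_map(shifted, truth.surfaces)
        assert np.allclose(m1.values, m2.values, equal_nan=True)
        assert np.allclose(m2.x_um, m1.x_um - 9 * volume.lateral_scale)
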