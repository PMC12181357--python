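"""Grid geometry, FCP preprocessing, registration, and map sampling."""

import math

import numpy as np
import pytest

from conftest import uniform_map
from ezreflect import phantom, structfunc
from ezreflect.structfunc import (
    AffineTransform,
    crop_window,
    etdrs_central,
    make_grid,
    preprocess_fcp,
    register,
    sample_points,
)

IDENTITY = AffineTransform(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))


class TestMakeGrid:
    def test_default_layout_counts(self):
        grid = make_grid()
        counts = grid.points.groupby("eccentricity_deg").size()
        assert len(grid.points) == 33
        assert counts.to_dict() == {0.0: 1, 1.0: 8, 3.0: 8, 5.0: 8, 7.0: 8}
        assert grid.sampling_diameter == pytest.approx(2 * 0.43)

    def test_rotation_preserves_eccentricity_multiset(self):
        g0 = make_grid()
        g45 = make_grid(rotation_deg=45.0)
        assert sorted(g0.points["eccentricity_deg"]) == sorted(g45.points["eccentricity_deg"])
        r0 = np.hypot(g0.points["x_deg"], g0.points["y_deg"])
        r45 = np.hypot(g45.points["x_deg"], g45.points["y_deg"])
        assert np.allclose(sorted(r0), sorted(r45))

    def test_wrong_total_rejected(self):
        with pytest.raises(ValueError, match="expected 33"):
            make_grid({0: 1, 1: 8, 3: 8, 5: 8, 7: 7})
        make_grid({0: 1, 1: 8, 3: 8, 5: 8, 7: 7}, allow_other_total=True)


class TestPreprocessFCP:
    def test_identity_passthrough(self):
        img = np.random.default_rng(0).random((768, 768))
        assert preprocess_fcp(img, source_fov=30.0) is img

    def test_crop_geometry_36_degrees(self):
        assert crop_window(1024, 36.0) == (85, 938)  # 853-px central window
        img = np.zeros((1024, 1024))
        out = preprocess_fcp(img, source_fov=36.0)
        assert out.shape == (768, 768)

    def test_small_fov_rejected(self):
        with pytest.raises(ValueError, match="below"):
            preprocess_fcp(np.zeros((512, 512)), source_fov=20.0)

    def test_frame_change_roundtrip(self, pathology_phantom):
        """An FCP render in a wider frame maps back onto the cSLO image."""
        _, truth = pathology_phantom
        eye = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        pair = phantom.render_nir_pair(
            truth, eye, seed=3, size=256, fcp_size=384, fcp_fov=36.0
        )
        back = preprocess_fcp(pair.fcp, source_fov=36.0, out_size=256)
        inner = slice(32, 224)
        assert np.abs(back[inner, inner] - pair.cslo[inner, inner]).mean() < 0.01


class TestRegister:
    def test_identity_pair(self, pathology_phantom):
        _, truth = pathology_phantom
        img = phantom.render_nir_texture(truth, seed=4)
        tf = register(img, img)
        assert not tf.failed
        assert tf.residual < 0.5
        assert np.allclose(tf.matrix, IDENTITY.matrix, atol=0.05)

    def test_known_translation_recovered(self, pathology_phantom):
        _, truth = pathology_phantom
        A = np.array([[1.0, 0.0, 12.0], [0.0, 1.0, -7.0]])
        pair = phantom.render_nir_pair(truth, A, seed=5)
        tf = register(pair.cslo, pair.fcp)
        assert not tf.failed
        assert abs(tf.matrix[0, 2] - 12.0) < 1.0
        assert abs(tf.matrix[1, 2] + 7.0) < 1.0

    def test_pure_noise_flags_failure(self, pathology_phantom):
        _, truth = pathology_phantom
        rng = np.random.default_rng(6)
        structured = phantom.render_nir_texture(truth, seed=6)
        noise = rng.random(structured.shape)
        tf = register(structured, noise, refine=False)
        assert tf.failed
        with pytest.raises(ValueError, match="refusing to sample"):
            sample_points(uniform_map(), make_grid(), tf)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            AffineTransform(np.array([[1.0, 0.0, 0.0], [2.0, 0.0, 0.0]]))


class TestSamplePoints:
    def test_uniform_map_full_coverage(self):
        m = uniform_map(value=5.0)
        samples = sample_points(m, make_grid(), IDENTITY)
        assert len(samples) == 33
        assert np.allclose(samples["mean_rezr"], 5.0)
        assert (samples["coverage"] == 1.0).all()

    def test_half_masked_disc(self):
        m = uniform_map(value=4.0, n_bscans=161, n_rois=96, spacing_um=45.0)
        # exclude everything left of the fovea: the 0-deg disc is half covered
        m.exclusions["atrophy"][:, : 96 // 2] = True
        samples = sample_points(m, make_grid(), IDENTITY, min_coverage=0.3)
        center = samples[samples["eccentricity_deg"] == 0].iloc[0]
        assert center["mean_rezr"] == pytest.approx(4.0)
        assert center["coverage"] == pytest.approx(0.5, abs=0.1)

    def test_delta_map_hits_unique_point(self):
        m = uniform_map(value=0.0)
        grid = make_grid()
        target = grid.points[grid.points["eccentricity_deg"] == 0].iloc[0]
        bi = int(np.argmin(np.abs(m.y_deg - target["y_deg"])))
        ri = int(np.argmin(np.abs(m.x_deg - target["x_deg"])))
        m.values[bi, ri] = 9.0
        samples = sample_points(m, grid, IDENTITY, min_coverage=0.0)
        nonzero = samples[samples["mean_rezr"] > 0]
        assert list(nonzero["point_id"]) == [int(target["point_id"])]

    def test_cell_selection_matches_bruteforce_distance_scan(self):
        m = uniform_map(value=1.0, n_bscans=161, n_rois=96, spacing_um=45.0)
        rng = np.random.default_rng(7)
        m.values += rng.random(m.values.shape)
        grid = make_grid()
        samples = sample_points(m, grid, IDENTITY)
        radius = grid.sampling_diameter / 2.0
        temporal = grid.points[
            (grid.points["eccentricity_deg"] == 7) & (grid.points["azimuth_deg"] == 0)
        ].iloc[0]
        vals = []
        for b in range(m.shape[0]):
            for r in range(m.shape[1]):
                d = math.hypot(m.x_deg[r] - 7.0, m.y_deg[b] - 0.0)
                if d <= radius:
                    vals.append(m.values[b, r])
        got = samples[samples["point_id"] == int(temporal["point_id"])].iloc[0]
        assert got["mean_rezr"] == pytest.approx(np.mean(vals))
        assert got["n_rois_included"] == len(vals)

    def test_point_outside_scan_has_zero_coverage(self):
        m = uniform_map(value=2.0, n_bscans=21, n_rois=10, spacing_um=45.0)  # tiny scan
        samples = sample_points(m, make_grid(), IDENTITY)
        outer = samples[samples["eccentricity_deg"] == 7]
        assert (outer["coverage"] == 0.0).all()
        assert outer["mean_rezr"].isna().all()

    def test_coverage_monotone_under_growing_exclusions(self):
        grid = make_grid()
        m = uniform_map(value=3.0, n_bscans=161, n_rois=96, spacing_um=45.0)
        cov_prev = sample_points(m, grid, IDENTITY)["coverage"]
        rng = np.random.default_rng(8)
        mask = np.zeros(m.values.shape, dtype=bool)
        for _ in range(3):
            mask |= rng.random(m.values.shape) < 0.2
            m.exclusions["drusen"][:] = mask
            cov = sample_points(m, grid, IDENTITY, min_coverage=0.0)["coverage"]
            assert (cov <= cov_prev + 1e-12).all()
            assert (cov <= 1.0).all()
            cov_prev = cov


class TestEtdrsCentral:
    def test_uniform_map(self):
        assert etdrs_central(uniform_map(value=6.5)) == pytest.approx(6.5)

    def test_step_map_sees_only_inner_value(self):
        m = uniform_map(value=2.0, n_bscans=161, n_rois=96, spacing_um=45.0)
        dist = np.hypot(
            m.x_um[None, :], m.y_um[:, None]
        )
        m.values[dist > 700.0] = 9.0  # outer value beyond the 500-um radius
        assert etdrs_central(m, diameter_mm=1.0) == pytest.approx(2.0)

    def test_fully_excluded_disc_flagged(self):
        m = uniform_map(value=1.0)
        m.exclusions["atrophy"][:] = True
        assert math.isnan(etdrs_central(m))
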