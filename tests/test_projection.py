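"""Depth-map projection: sampling, rasterization, calibration, round trips."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from occlumap.projection import (
    DepthMap,
    ProjectionConfig,
    backproject,
    canonicalize_cloud_inplane,
    canonicalize_inplane,
    downsample_max,
    normalize_z,
    project_depth,
    projection_rmse_mm,
    repeatability_ci,
    sample_surface,
)


@pytest.fixture(scope="module")
def unit_square():
    return trimesh.Trimesh(
        vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
        faces=[[0, 1, 2], [0, 2, 3]],
        process=False,
    )


class TestSampleSurface:
    def test_uniform_density(self, unit_square):
        n = 100_000
        cloud = sample_surface(unit_square, n, seed=1)
        # quadrant counts within 3 sigma of the binomial expectation
        q = (cloud.points[:, 0] > 0.5).astype(int) * 2 + (
            cloud.points[:, 1] > 0.5
        )
        counts = np.bincount(q, minlength=4)
        sigma = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - n / 4) < 3 * sigma)

    def test_zero_samples_rejected(self, unit_square):
        with pytest.raises(ValueError):
            sample_surface(unit_square, 0)

    def test_deterministic_per_seed(self, unit_square):
        a = sample_surface(unit_square, 1000, seed=3)
        b = sample_surface(unit_square, 1000, seed=3)
        np.testing.assert_array_equal(a.points, b.points)
        np.testing.assert_array_equal(a.normals, b.normals)


class TestNormalizeZ:
    def test_already_at_window_top(self):
        pts = np.array([[0, 0, 8.0], [1, 1, 2.0]])
        np.testing.assert_array_equal(normalize_z(pts, 8.0), pts)

    def test_shift_amount(self):
        pts = np.array([[0, 0, 0.0], [1, 0, -3.0]])
        out = normalize_z(pts, 8.0)
        np.testing.assert_allclose(out[:, 2], [8.0, 5.0])
        np.testing.assert_array_equal(out[:, :2], pts[:, :2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_max_z_exact(self, seed):
        pts = np.random.default_rng(seed).normal(size=(50, 3)) * 3
        out = normalize_z(pts, 8.0)
        assert abs(out[:, 2].max() - 8.0) < 1e-12


class TestProjectDepth:
    def test_point_at_window_top_is_255(self):
        cfg = ProjectionConfig(resolution=64, n_sample=1)
        dm = project_depth(
            np.array([[0.0, 0.0, 8.0]]), cfg, xy_offset=np.zeros(2)
        )
        assert dm.quantized().max() == 255
        assert (dm.quantized() > 0).sum() == 1

    def test_point_below_window_is_background(self):
        cfg = ProjectionConfig(resolution=64, n_sample=1)
        dm = project_depth(
            np.array([[0.0, 0.0, -1.0]]), cfg, xy_offset=np.zeros(2)
        )
        assert dm.quantized().sum() == 0

    def test_flat_plate_scaling_rule(self):
        """A plate at half window depth covers k pixels of round(127.5)."""
        cfg = ProjectionConfig(resolution=64, n_sample=1)
        g = np.linspace(-1.99, 1.99, 80)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack(
            [xx.ravel(), yy.ravel(), np.full(xx.size, 4.0)]
        )
        dm = project_depth(pts, cfg, xy_offset=np.zeros(2))
        q = dm.quantized()
        vals = q[q > 0]
        assert np.all(vals == 128)  # round-half-away of 127.5
        assert len(vals) == 16 * 16  # 4 mm plate at 0.25 mm pixels

    def test_points_outside_plane_rejected(self):
        cfg = ProjectionConfig(resolution=64, plane_size=16.0, n_sample=1)
        with pytest.raises(ValueError, match="plane"):
            project_depth(
                np.array([[20.0, 0.0, 4.0]]), cfg, xy_offset=np.zeros(2)
            )

    def test_non_power_of_two_resolution_rejected(self):
        with pytest.raises(ValueError):
            ProjectionConfig(resolution=100)

    def test_calibration_round_trip_exact(self):
        cfg = ProjectionConfig(resolution=64, n_sample=1)
        dm = project_depth(
            np.array([[0.0, 0.0, 8.0]]), cfg, xy_offset=np.zeros(2)
        )
        mesh = backproject(dm, cfg)
        assert mesh.vertices[:, 2].max() == pytest.approx(cfg.z_norm, abs=0)


class TestDownsampleMax:
    def test_matches_direct_coarse_projection(self):
        """Block max of a fine map equals projecting the same cloud on the
        coarse grid (pixels nest, max of maxes)."""
        rng = np.random.default_rng(12)
        pts = np.column_stack(
            [rng.uniform(-6, 6, (20_000, 2)), rng.uniform(0.5, 8.0, 20_000)]
        )
        fine = project_depth(
            pts, ProjectionConfig(resolution=128, n_sample=1),
            xy_offset=np.zeros(2),
        )
        coarse = project_depth(
            pts, ProjectionConfig(resolution=64, n_sample=1),
            xy_offset=np.zeros(2),
        )
        np.testing.assert_array_equal(
            downsample_max(fine).pixels, coarse.pixels
        )

    def test_invalid_factor(self):
        dm = DepthMap(np.zeros((64, 64)), 8.0, 16.0)
        with pytest.raises(ValueError):
            downsample_max(dm, factor=3)


class TestCanonicalizeInplane:
    def _tooth_map(self, truth_projection):
        return truth_projection.dmap

    def test_idempotent(self, truth_projection):
        canon, pose1 = canonicalize_inplane(truth_projection.dmap)
        again, pose2 = canonicalize_inplane(canon)
        assert abs(pose2.angle_deg) < 0.5
        assert np.hypot(*pose2.translation_px) < 0.5

    def test_round_trip_after_rotation(self, truth_projection):
        from skimage.transform import rotate

        canon, _ = canonicalize_inplane(truth_projection.dmap)
        rotated = canon.copy_with(
            rotate(canon.pixels, angle=30, order=1, preserve_range=True)
        )
        recovered, pose = canonicalize_inplane(rotated)
        assert abs(abs(pose.angle_deg) - 30) < 1.5
        diff = np.abs(
            recovered.quantized().astype(float)
            - canon.quantized().astype(float)
        )
        assert diff.mean() <= 2.0  # interpolation-level agreement

    def test_buccal_hint_resolves_half_turn(self, truth_projection):
        hint = (0.0, -1.0)
        canon, _ = canonicalize_inplane(truth_projection.dmap, buccal_hint=hint)
        # index flip = half turn about the continuous image center
        flipped = canon.copy_with(canon.pixels[::-1, ::-1].copy())
        # after a half turn the buccal side points the other way
        recovered, pose = canonicalize_inplane(flipped, buccal_hint=(0.0, 1.0))
        diff = np.abs(
            recovered.quantized().astype(float)
            - canon.quantized().astype(float)
        )
        assert diff.mean() <= 2.0

    def test_empty_foreground_rejected(self):
        dm = DepthMap(np.zeros((64, 64)), 8.0, 16.0)
        with pytest.raises(ValueError):
            canonicalize_inplane(dm)

    def test_cloud_canonicalization_centers_rect(self, truth_projection):
        pts = truth_projection.cloud.points.copy()
        pts[:, 2] += truth_projection.z_shift
        out, rot, center = canonicalize_cloud_inplane(pts, buccal_hint=(0, -1))
        lo, hi = out[:, :2].min(axis=0), out[:, :2].max(axis=0)
        np.testing.assert_allclose((lo + hi) / 2, [0, 0], atol=0.05)


class TestRmse:
    def _map(self, arr):
        return DepthMap(np.asarray(arr, float), 8.0, 16.0)

    def test_identical_maps_zero(self, truth_projection):
        assert projection_rmse_mm(
            truth_projection.dmap, truth_projection.dmap
        ) == 0.0

    def test_single_pixel_closed_form(self):
        a = np.zeros((256, 256))
        b = np.zeros((256, 256))
        b[3, 7] = 255.0
        expected = (255.0 / 256.0) * (8.0 / 255.0)
        assert projection_rmse_mm(self._map(a), self._map(b)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_uniform_unit_difference(self):
        a = np.full((64, 64), 100.0)
        b = np.full((64, 64), 101.0)
        assert projection_rmse_mm(self._map(a), self._map(b)) == pytest.approx(
            8.0 / 255.0, rel=1e-12
        )

    def test_symmetry_and_calibration_check(self):
        a, b = self._map(np.zeros((64, 64))), self._map(np.ones((64, 64)))
        assert projection_rmse_mm(a, b) == projection_rmse_mm(b, a)
        with pytest.raises(ValueError):
            projection_rmse_mm(a, DepthMap(np.ones((64, 64)), 4.0, 16.0))

    def test_background_inclusion_identity(self):
        """RMSE_incl = RMSE_excl * sqrt(fraction nonzero) when differences
        live only on the joint foreground."""
        rng = np.random.default_rng(8)
        a = np.zeros((64, 64))
        a[20:40, 20:40] = rng.uniform(50, 200, (20, 20))
        b = a.copy()
        b[20:40, 20:40] += rng.uniform(0, 5, (20, 20))
        da, db = self._map(a), self._map(b)
        incl = projection_rmse_mm(da, db, background="include")
        excl = projection_rmse_mm(da, db, background="exclude")
        frac = (da.foreground() | db.foreground()).mean()
        assert incl == pytest.approx(excl * np.sqrt(frac), rel=1e-9)


class TestRepeatability:
    def test_ci_ordering_and_zero_case(self, normalized):
        cfg = ProjectionConfig(resolution=64, n_sample=20_000)
        lo, hi = repeatability_ci(normalized.mesh, cfg, n_rep=5)
        assert lo <= hi
        # identical sampling seeds give identical maps, RMSE exactly 0
        a = sample_surface(normalized.mesh, 10_000, seed=4)
        b = sample_surface(normalized.mesh, 10_000, seed=4)
        da = project_depth(normalize_z(a.points, 8.0), cfg)
        db = project_depth(normalize_z(b.points, 8.0), cfg)
        assert projection_rmse_mm(da, db) == 0.0

    def test_needs_two_repetitions(self, normalized):
        cfg = ProjectionConfig(resolution=64, n_sample=1000)
        with pytest.raises(ValueError):
            repeatability_ci(normalized.mesh, cfg, n_rep=1)


class TestBackproject:
    def test_block_geometry(self):
        cfg = ProjectionConfig(resolution=64, n_sample=1)
        px = np.zeros((64, 64))
        px[10:12, 20:22] = 255.0
        mesh = backproject(DepthMap(px, 8.0, 16.0), cfg)
        assert len(mesh.vertices) == 4
        assert len(mesh.faces) == 2
        np.testing.assert_allclose(mesh.vertices[:, 2], 8.0)

    def test_all_zero_rejected(self):
        cfg = ProjectionConfig(resolution=64, n_sample=1)
        with pytest.raises(ValueError):
            backproject(DepthMap(np.zeros((64, 64)), 8.0, 16.0), cfg)

    def test_monotone_ramp_heights(self):
        cfg = ProjectionConfig(resolution=64, n_sample=1)
        px = np.zeros((64, 64))
        px[30, 10:30] = np.linspace(50, 250, 20)
        mesh = backproject(DepthMap(px, 8.0, 16.0), cfg)
        order = np.argsort(mesh.vertices[:, 0])
        z = mesh.vertices[order, 2]
        assert np.all(np.diff(z) > 0)

    def test_projection_round_trip_smooth_map(self):
        """Re-projecting the back-projected mesh reproduces a smooth map."""
        cfg = ProjectionConfig(resolution=64, n_sample=1)
        jj, ii = np.meshgrid(np.arange(64), np.arange(64))
        r2 = (ii - 32.0) ** 2 + (jj - 32.0) ** 2
        px = np.where(r2 < 24**2, 80.0 + 60.0 * np.exp(-r2 / 800.0), 0.0)
        dm = DepthMap(px, 8.0, 16.0)
        mesh = backproject(dm, cfg)
        cloud = sample_surface(mesh, 400_000, seed=5)
        re = project_depth(cloud.points, cfg, xy_offset=np.zeros(2))
        a = dm.quantized().astype(float)
        b = re.quantized().astype(float)
        assert np.abs(a - b).mean() <= 1.0
        assert projection_rmse_mm(dm, re) < 2 * dm.c_pix_mm
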