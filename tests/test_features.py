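"""Density, relative volume, granulometry, fractal dimension, sphericity."""

import numpy as np
import pytest

from mlsct import (
    CalibrationContext,
    CTVolume,
    VoxelMask,
    density,
    fractal_dimension,
    gmm_density,
    granulometry_avg,
    relative_volume,
    sphericity,
)
from mlsct.compartments import GMMFit


def ball_mask(radius, pad=3):
    n = 2 * int(np.ceil(radius)) + 1 + 2 * pad
    c = n // 2
    g = np.ogrid[:n, :n, :n]
    return VoxelMask(sum((x - c) ** 2 for x in g) <= radius**2, f"ball{radius}")


class TestDensity:
    def test_uniform_voi(self):
        vol = CTVolume(np.full((4, 4, 4), 35.0, dtype=np.float32))
        voi = VoxelMask(np.ones((4, 4, 4), bool), "v")
        assert density(vol, voi, CalibrationContext(0.0, -100.0)) == pytest.approx(35.0)

    def test_water_shift_moves_density_exactly(self):
        vol = CTVolume(np.full((4, 4, 4), 35.0, dtype=np.float32))
        voi = VoxelMask(np.ones((4, 4, 4), bool), "v")
        ctx = CalibrationContext(0.0, -100.0)
        d0 = density(vol, voi, ctx)
        d1 = density(vol, voi, ctx.shifted_h2o(5.0))
        assert d1 - d0 == pytest.approx(-5.0, abs=1e-9)

    def test_zero_mean_noise_bounded_by_standard_error(self):
        rng = np.random.default_rng(0)
        base = np.zeros((40, 40, 40), dtype=np.float32)
        vol0 = CTVolume(base)
        vol1 = CTVolume(base + rng.normal(0, 10, base.shape).astype(np.float32))
        voi = VoxelMask(np.ones(base.shape, bool), "v")
        ctx = CalibrationContext(0.0, -100.0)
        d = abs(density(vol1, voi, ctx) - density(vol0, voi, ctx))
        assert d <= 3 * 10.0 / np.sqrt(base.size)

    def test_empty_voi_rejected(self):
        vol = CTVolume(np.zeros((3, 3, 3), dtype=np.float32))
        with pytest.raises(ValueError, match="empty"):
            density(vol, VoxelMask(np.zeros((3, 3, 3), bool), "v"), CalibrationContext(0.0, -100.0))


class TestGmmDensity:
    def setup_method(self):
        self.fit = GMMFit(1.0, -100.0, 10.0, 1.0, 35.0, 12.0, -30.0, 0.0, converged=True)

    def test_component_peaks_minus_water(self):
        ctx = CalibrationContext(ct_h2o=-2.0, ct_at=-110.0)
        assert gmm_density(self.fit, "MT", ctx) == pytest.approx(37.0)
        assert gmm_density(self.fit, "AT", ctx) == pytest.approx(-98.0)

    def test_flagged_fit_and_bad_component(self):
        ctx = CalibrationContext(0.0, -100.0)
        bad = GMMFit(1, -100, 10, 1, 35, 12, -30, 0.0, converged=False)
        with pytest.raises(ValueError):
            gmm_density(bad, "MT", ctx)
        with pytest.raises(ValueError):
            gmm_density(self.fit, "XX", ctx)


class TestRelativeVolume:
    def test_identity_and_disjoint(self):
        a = VoxelMask(np.ones((4, 4, 4), bool), "a")
        assert relative_volume(a, a) == 1.0
        b = VoxelMask(np.zeros((4, 4, 4), bool), "b")
        b.data[0, 0, 0] = True
        c = VoxelMask(np.zeros((4, 4, 4), bool), "c")
        c.data[3, 3, 3] = True
        with pytest.warns(UserWarning, match="not contained"):
            assert relative_volume(b, c) == 0.0

    def test_empty_reference_rejected(self):
        a = VoxelMask(np.ones((4, 4, 4), bool), "a")
        with pytest.raises(ValueError):
            relative_volume(a, VoxelMask(np.zeros((4, 4, 4), bool), "ref"))

    def test_phantom_sat_fraction_matches_truth(self, bundle_noisy, phantom_noisy):
        from conftest import slab_restrict
        _, gt = phantom_noisy
        rv = relative_volume(bundle_noisy.voi_sat, bundle_noisy.voi_mls)
        truth_sat = slab_restrict(gt.sat_region().data).sum()
        truth_mls = truth_sat + slab_restrict(gt.intrafascia().data).sum()
        assert rv == pytest.approx(truth_sat / truth_mls, rel=0.03)


class TestGranulometry:
    def test_single_ball_diameter(self):
        assert granulometry_avg(ball_mask(5.0)) == pytest.approx(10.0, abs=1.0)

    def test_two_grain_classes_volume_weighted(self):
        grid = np.zeros((80, 40, 40), bool)
        b6 = ball_mask(3.0, pad=0).data
        b12 = ball_mask(6.0, pad=0).data
        for p in [(5, 5, 5), (5, 5, 25), (5, 25, 5), (5, 25, 25),
                  (25, 5, 5), (25, 5, 25), (25, 25, 5), (25, 25, 25)]:
            grid[p[0]:p[0] + b6.shape[0], p[1]:p[1] + b6.shape[1], p[2]:p[2] + b6.shape[2]] |= b6
        grid[50:50 + b12.shape[0], 10:10 + b12.shape[1], 10:10 + b12.shape[2]] |= b12
        # eight d=6 balls and one d=12 ball have (nearly) equal total volume
        v6 = 8 * b6.sum()
        v12 = b12.sum()
        oracle = (6.0 * v6 + 12.0 * v12) / (v6 + v12)
        assert granulometry_avg(VoxelMask(grid, "grains")) == pytest.approx(oracle, abs=1.0)

    def test_erosion_reduces_grain_size(self):
        from scipy import ndimage
        b = ball_mask(6.0)
        eroded = VoxelMask(ndimage.binary_erosion(b.data, iterations=2), "eroded")
        assert granulometry_avg(eroded) < granulometry_avg(b)

    def test_invariant_to_translation_and_rotation(self):
        m = np.zeros((30, 30, 30), bool)
        m[5:12, 8:18, 10:14] = True
        g0 = granulometry_avg(VoxelMask(m, "m"))
        assert granulometry_avg(VoxelMask(np.roll(m, 5, axis=2), "t")) == pytest.approx(g0, abs=1e-9)
        assert granulometry_avg(VoxelMask(np.rot90(m, axes=(0, 1)), "r")) == pytest.approx(g0, abs=1e-9)


class TestFractalDimension:
    def test_solid_cube_boundary_is_a_surface(self):
        m = np.zeros((70, 70, 70), bool)
        m[3:67, 3:67, 3:67] = True
        assert fractal_dimension(VoxelMask(m, "cube")) == pytest.approx(2.0, abs=0.15)

    def test_line_is_one_dimensional(self):
        m = np.zeros((70, 5, 5), bool)
        m[3:67, 2, 2] = True
        assert fractal_dimension(VoxelMask(m, "line")) == pytest.approx(1.0, abs=0.15)

    def test_too_few_scales_rejected(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        with pytest.raises(ValueError, match="scales"):
            fractal_dimension(VoxelMask(m, "tiny"))

    def test_invariant_to_translation_and_rotation(self):
        m = np.zeros((40, 40, 40), bool)
        m[5:30, 8:28, 10:24] = True
        f0 = fractal_dimension(VoxelMask(m, "m"))
        assert fractal_dimension(VoxelMask(np.roll(m, 6, axis=0), "t")) == pytest.approx(f0, abs=1e-9)
        assert fractal_dimension(VoxelMask(np.rot90(m, axes=(1, 2)), "r")) == pytest.approx(f0, abs=1e-9)


class TestSphericity:
    def test_ball_is_maximally_spherical(self):
        assert sphericity(ball_mask(20)) >= 0.97

    def test_cube_closed_form(self):
        m = np.zeros((30, 30, 30), bool)
        m[5:25, 5:25, 5:25] = True
        assert sphericity(VoxelMask(m, "cube")) == pytest.approx((np.pi / 6) ** (1 / 3), abs=0.03)

    def test_elongation_lowers_sphericity(self):
        rod = np.zeros((6, 6, 14), bool)
        rod[2:3, 2:3, 2:10] = True
        cube = np.zeros((8, 8, 8), bool)
        cube[2:4, 2:4, 2:4] = True
        assert sphericity(VoxelMask(rod, "rod")) < sphericity(VoxelMask(cube, "cube2"))

    def test_single_voxel_rejected(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        with pytest.raises(ValueError, match="too small"):
            sphericity(VoxelMask(m, "pt"))
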