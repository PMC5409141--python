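"""Tissue compartments: SAT/PAT/M set algebra, GMM decomposition, MT growing
and the muscle-concentration bins."""

import numpy as np
import pytest
from scipy import ndimage

from mlsct import (
    CalibrationContext,
    CTVolume,
    VoxelMask,
    concentration_bins,
    fit_gmm,
    gaussian_intersection,
    segment_mt,
    segment_pat_and_m,
    segment_sat,
)
from mlsct._morphology import boundary_voxels
from mlsct.calibration import TrimmedHistogram
from mlsct.compartments import BIN_CODES, GMMFit

from conftest import dilated_femur, slab_restrict


def _fake_star(mode=-105.0, sd=12.0, height=1000.0):
    centers = np.arange(mode - 40, mode + 41)
    return TrimmedHistogram(
        bin_centers=centers, counts=np.full(centers.size, 10.0), mode_hu=mode,
        mode_count=height, trim_bounds=(centers[0], centers[-1]),
        sym_mean=mode, sym_sd=sd,
    )


class TestSatSegmentation:
    def test_disjoint_from_if_and_dermis(self, bundle_noisy):
        assert not (bundle_noisy.voi_sat.data & bundle_noisy.voi_if.data).any()
        assert not (bundle_noisy.voi_sat.data & bundle_noisy.dermis.data).any()

    def test_dermis_shell_never_in_sat(self, bundle_noisy, phantom_noisy):
        _, gt = phantom_noisy
        assert not (bundle_noisy.voi_sat.data & gt.mask("dermis").data).any()

    def test_empty_sat_rejected(self):
        us = VoxelMask(np.ones((6, 6, 6), bool), "US")
        vif = VoxelMask(np.ones((6, 6, 6), bool), "IF")
        with pytest.raises(ValueError, match="empty"):
            segment_sat(us, vif, np.zeros((6, 6, 6), bool))


class TestPatAndM:
    def _scene(self):
        shape = (12, 12, 12)
        vif = np.zeros(shape, bool)
        vif[3:9, 3:9, 3:9] = True
        surface = boundary_voxels(vif)
        hu = np.full(shape, 40.0, dtype=np.float32)
        vol = CTVolume(hu)
        femur = VoxelMask(np.zeros(shape, bool), "femur")
        return vol, VoxelMask(vif, "IF"), surface, femur

    def test_strict_threshold_at_t_at(self):
        vol, vif, surface, femur = self._scene()
        vol.data[4, 4, 4] = -50.0   # == T_AT exactly -> not PAT
        vol.data[4, 7, 4] = -50.1   # < T_AT, fascia-adjacent -> PAT
        pat, m = segment_pat_and_m(vol, vif, surface, t_at=-50.0, femur_mask=femur)
        assert not pat.data[4, 4, 4] and m.data[4, 4, 4]
        assert pat.data[4, 7, 4] and not m.data[4, 7, 4]

    def test_isolated_lipid_island_stays_in_muscle(self):
        vol, vif, surface, femur = self._scene()
        vol.data[6, 6, 6] = -110.0  # deep interior, not fascia-connected
        pat, m = segment_pat_and_m(vol, vif, surface, t_at=-50.0, femur_mask=femur)
        assert not pat.data[6, 6, 6] and m.data[6, 6, 6]

    def test_compartments_tile_voi_if_exactly(self, bundle_noisy, phantom_noisy):
        b = bundle_noisy
        fem = ndimage.binary_dilation(
            b.femur.data, np.ones((3, 3, 3), bool), iterations=1
        )
        n_if = b.voi_if.count()
        n_parts = (
            b.voi_pat.count() + b.voi_m.count() + (fem & b.voi_if.data).sum()
        )
        assert n_parts == n_if
        assert not (b.voi_pat.data & b.voi_m.data).any()

    def test_recovers_phantom_pat_volume(self, bundle_noiseless, phantom_noiseless):
        _, gt = phantom_noiseless
        truth = slab_restrict(gt.mask("PAT").data).sum()
        assert abs(bundle_noiseless.voi_pat.count() - truth) / truth < 0.03


class TestGmm:
    @pytest.mark.parametrize(
        "sd_at,sd_mt,mean_tol,sd_rel_tol",
        [(12.0, 15.0, 1.0, 0.05), (20.0, 20.0, 2.0, 0.10)],
    )
    def test_parameter_recovery_from_sampled_mixture(self, sd_at, sd_mt, mean_tol, sd_rel_tol):
        rng = np.random.default_rng(3)
        n = 10**6
        vals = np.concatenate(
            [rng.normal(-105, sd_at, int(0.6 * n)), rng.normal(35, sd_mt, n - int(0.6 * n))]
        )
        vol = CTVolume(vals.reshape(100, 100, 100))
        voi = VoxelMask(np.ones((100, 100, 100), bool), "MLS")
        ctx = CalibrationContext(ct_h2o=0.0, ct_at=-105.0, n_voi_at=int(0.6 * n))
        fit = fit_gmm(vol, voi, _fake_star(sd=sd_at), ctx)
        assert fit.converged
        assert fit.at_mean == pytest.approx(-105.0, abs=mean_tol)
        assert fit.mt_mean == pytest.approx(35.0, abs=mean_tol)
        assert fit.at_sd == pytest.approx(sd_at, rel=sd_rel_tol)
        assert fit.mt_sd == pytest.approx(sd_mt, rel=sd_rel_tol)

    def test_equal_curves_intersect_at_midpoint(self):
        a = gaussian_intersection(1.0, -100.0, 10.0, 1.0, 40.0, 10.0)
        assert a == pytest.approx(-30.0)

    def test_intersection_matches_grid_scan_oracle(self):
        h1, m1, s1, h2, m2, s2 = 1.0, -105.0, 12.0, 0.7, 35.0, 15.0
        x = np.arange(m1, m2, 0.01)
        c1 = h1 * np.exp(-((x - m1) ** 2) / (2 * s1**2))
        c2 = h2 * np.exp(-((x - m2) ** 2) / (2 * s2**2))
        oracle = x[np.argmin(np.abs(c1 - c2))]
        assert gaussian_intersection(h1, m1, s1, h2, m2, s2) == pytest.approx(oracle, abs=0.01)

    def test_invariants_on_pipeline_fit(self, bundle_noisy):
        fit = bundle_noisy.gmm_mls
        assert fit.converged
        assert fit.at_mean < fit.intersection_a < fit.mt_mean == fit.peak_b
        assert fit.at_sd > 0 and fit.mt_sd > 0


class TestMuscleTissue:
    def test_noiseless_equals_threshold_oracle(self, bundle_noiseless, phantom_noiseless):
        vol, gt = phantom_noiseless
        b = bundle_noiseless
        fem = dilated_femur(gt)
        domain = b.voi_if.data & ~fem
        accept = (vol.data > b.gmm_mls.intersection_a) & domain
        seeds = (vol.data > b.gmm_mls.peak_b) & domain
        labels, _ = ndimage.label(accept, structure=np.ones((3, 3, 3), bool))
        keep = np.unique(labels[seeds])
        oracle = np.isin(labels, keep[keep > 0])
        assert np.array_equal(b.voi_mt.data, oracle)

    def test_mt_contained_in_m(self, bundle_noiseless):
        b = bundle_noiseless
        assert not (b.voi_mt.data & ~b.voi_m.data).any()

    def test_lone_supra_peak_island_kept(self):
        shape = (9, 9, 9)
        hu = np.full(shape, -10.0, dtype=np.float32)  # below intersection a
        hu[4, 4, 4] = 60.0                            # above peak b
        vol = CTVolume(hu)
        vif = VoxelMask(np.ones(shape, bool), "IF")
        fit = GMMFit(
            at_height=1.0, at_mean=-100.0, at_sd=10.0, mt_height=1.0,
            mt_mean=50.0, mt_sd=10.0, intersection_a=0.0,
            residual_norm=0.0, converged=True,
        )
        mt = segment_mt(vol, vif, fit, VoxelMask(np.zeros(shape, bool), "femur"))
        assert mt.data[4, 4, 4] and mt.count() == 1

    def test_flagged_fit_refused(self):
        fit = GMMFit(1, -100, 10, 1, 50, 10, 0.0, 0.0, converged=False)
        vol = CTVolume(np.zeros((4, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="non-convergent"):
            segment_mt(vol, VoxelMask(np.ones((4, 4, 4), bool), "IF"), fit,
                       VoxelMask(np.zeros((4, 4, 4), bool), "femur"))


class TestConcentrationBins:
    def _ctx(self):
        # T_AT = -80, CT_H2O = 5 -> T_HDM = 40
        return CalibrationContext(ct_h2o=5.0, ct_at=-100.0, t_at=-80.0)

    @pytest.mark.parametrize(
        "hu,bin_name",
        [
            (40.0, "B6"),    # == T_HDM -> 100% -> HDM
            (-80.0, "B2"),   # == T_AT -> 0% is the lower edge of B2
            (-20.0, "B4"),   # midway -> 50%
            (-80.5, "IMAT"), # below T_AT -> negative concentration
            (100.0, "B6"),   # > 100% still HDM
            (-50.3, "B2"),   # 24.75% floors to 24, still B2
            (-50.0, "B3"),   # exactly 25%
        ],
    )
    def test_printed_bin_edges(self, hu, bin_name):
        ctx = self._ctx()
        expected = bin_name
        vol = CTVolume(np.full((3, 3, 3), hu, dtype=np.float32))
        vif = VoxelMask(np.ones((3, 3, 3), bool), "IF")
        fem = VoxelMask(np.zeros((3, 3, 3), bool), "femur")
        cmap = concentration_bins(vol, vif, ctx, fem)
        assert cmap.bin_labels[1, 1, 1] == BIN_CODES[expected]

    def test_bins_partition_domain(self, bundle_noisy):
        cmap = bundle_noisy.concentration
        assert sum(cmap.counts().values()) == cmap.domain.sum()
        assert not (cmap.bin_labels > 0)[~cmap.domain].any()
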