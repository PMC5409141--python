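"""Hierarchical fascia segmentation: grades, aggregation, components,
candidates, ray-reflection shielding and the final smoothing."""

import numpy as np
import pytest
from scipy import ndimage

from mlsct import (
    CalibrationContext,
    CTVolume,
    aggregation_map,
    classify_potential_muscle,
    compactify,
    contrast_map,
    find_candidate_voxels,
    finalize_if,
    grade_params,
    ray_shielding,
    select_leg_components,
)
from mlsct._morphology import DIRECTIONS26, boundary_voxels
from mlsct.config import ConfigError
from mlsct.fascia import NOT_SHIELDED, SHIELDED, dermis_connected_mask

from conftest import make_phantom


class TestGradeParams:
    @pytest.mark.parametrize(
        "G,cmin,amin",
        [(1, 0.60, 0.80), (2, 0.45, 0.75), (3, 0.30, 0.70)],
    )
    def test_printed_formulas(self, G, cmin, amin):
        gp = grade_params(G)
        assert gp.c_min == pytest.approx(cmin)
        assert gp.alpha_min == pytest.approx(amin)

    @pytest.mark.parametrize("G", [0, 4])
    def test_out_of_range_grade(self, G):
        with pytest.raises(ConfigError, match="range"):
            grade_params(G)


class TestAggregation:
    def test_uniform_neighborhoods(self):
        c = np.ones((5, 5, 5))
        a = aggregation_map(c, 0.5)
        assert a[2, 2, 2] == 1.0  # all 26 neighbors pass
        c[:, :, :2] = 0.0  # half fails
        a = aggregation_map(c, 0.5)
        # center column at k=2: 9 of its neighbors sit at k=1 and fail
        assert a[2, 2, 2] == pytest.approx(17 / 26)

    def test_matches_exhaustive_neighbor_enumeration(self):
        rng = np.random.default_rng(4)
        c = rng.uniform(0, 1, size=(7, 6, 5))
        body = rng.random((7, 6, 5)) > 0.2
        a = aggregation_map(c, 0.5, body)
        for v in [(0, 0, 0), (3, 3, 2), (6, 5, 4), (1, 4, 3)]:
            count = 0
            for d in DIRECTIONS26:
                p = tuple(np.add(v, d))
                if all(0 <= p[i] < c.shape[i] for i in range(3)):
                    if body[p] and c[p] >= 0.5:
                        count += 1
            assert a[v] == pytest.approx(count / 26)

    def test_ties_pass(self):
        c = np.full((3, 3, 3), 0.5)
        assert aggregation_map(c, 0.5)[1, 1, 1] == pytest.approx(1.0)


class TestPotentialMuscle:
    def test_shallow_and_disconnected_voxels_excluded(self):
        shape = (40, 20, 10)
        body = np.ones(shape, bool)
        c = np.zeros(shape)
        c[15:25, 8:14, :] = 1.2          # deep muscle block
        c[2, 2, :] = 1.2                 # shallow dermis-like line (depth < 10)
        c[32:35, 8:12, :] = 1.2          # high-C blob away from the femur
        femur = np.zeros(shape, bool)
        femur[19:21, 10:12, :] = True
        alpha = aggregation_map(c, 0.6, body)
        kept = classify_potential_muscle(c, alpha, grade_params(1), femur, body)
        assert kept[20, 10, 5]
        assert not kept[2, 2, 5]         # condition 1: depth
        assert not kept[33, 10, 5]       # condition 2: femur connection

    def test_monotone_in_grade(self, phantom_noisy, bundle_noisy):
        vol, gt = phantom_noisy
        ctx = bundle_noisy.ctx
        cmap = contrast_map(vol, ctx)
        body = bundle_noisy.body.data
        fem = gt.mask("femur").data
        masks = {}
        for G in (1, 3):
            gp = grade_params(G)
            alpha = aggregation_map(cmap, gp.c_min, body)
            masks[G] = classify_potential_muscle(cmap, alpha, gp, fem, body)
        assert not (masks[1] & ~masks[3]).any()  # G=3 thresholds are laxer


class TestLegComponents:
    def test_two_legs_with_laterality(self, bundle_noisy, phantom_noisy):
        _, gt = phantom_noisy
        fem = gt.mask("femur").data
        right = bundle_noisy.voi_ifa.data.copy()
        legs = select_leg_components(right, fem)
        assert set(legs) == {"right", "left"}
        assert ndimage.center_of_mass(legs["right"])[0] < ndimage.center_of_mass(legs["left"])[0]

    def test_artifact_blob_dropped(self):
        m = np.zeros((30, 10, 5), bool)
        m[2:10] = True          # large
        m[14:21] = True         # large
        m[26:27, 0:2, 0:2] = True  # small artifact
        fem = np.zeros_like(m)
        fem[5, 5, 2] = fem[17, 5, 2] = True
        legs = select_leg_components(m, fem)
        assert not any(comp[26, 0, 0] for comp in legs.values())

    def test_single_leg_warns(self):
        m = np.zeros((10, 10, 5), bool)
        m[2:8, 2:8, :] = True
        with pytest.warns(UserWarning, match="single leg"):
            legs = select_leg_components(m, np.zeros_like(m))
        assert len(legs) == 1


class TestCompactify:
    def test_holes_removed_and_extensive(self):
        m = np.zeros((24, 24, 24), bool)
        m[4:20, 4:20, 4:20] = True
        m[10:13, 10:13, 10:13] = False  # interior cavity
        out = compactify(m)
        assert out[11, 11, 11]
        assert not (m & ~out).any()  # closing + filling never removes voxels

    def test_fa_close_to_true_fascia_without_rind(self):
        vol, gt = make_phantom(noise_sd=0.0, pat_rind_thickness_vox=0, eml_speckle_density=0.0)
        ctx = CalibrationContext(ct_h2o=0.0, ct_at=-100.0)
        cmap = contrast_map(vol, ctx)
        body = gt.labels > 0
        gp = grade_params(1)
        alpha = aggregation_map(cmap, gp.c_min, body)
        kept = classify_potential_muscle(cmap, alpha, gp, gt.mask("femur").data, body)
        legs = select_leg_components(kept, gt.mask("femur").data)
        fa = boundary_voxels(compactify(next(iter(legs.values()))))
        fascia = gt.mask("fascia").data
        dist = ndimage.distance_transform_edt(~fascia)
        assert dist[fa].mean() <= 2.0


class TestCandidates:
    def _scene(self):
        """Solid block (IFA) with probe voxels in front of its face."""
        shape = (12, 9, 9)
        hu = np.full(shape, -100.0, dtype=np.float32)  # adipose background
        ifa = np.zeros(shape, bool)
        ifa[:3] = True
        hu[ifa] = 40.0
        vol = CTVolume(hu)
        ctx = CalibrationContext(ct_h2o=0.0, ct_at=-100.0)
        return vol, ctx, ifa

    def _run(self, vol, ctx, ifa):
        cmap = contrast_map(vol, ctx)
        dermis = np.zeros(vol.shape, bool)
        return find_candidate_voxels(vol, cmap, ifa, dermis)[0]

    def test_high_contrast_voxel_accepted(self):
        vol, ctx, ifa = self._scene()
        vol.data[3, 4, 4] = 20.0  # C = 1.2
        assert self._run(vol, ctx, ifa)[3, 4, 4]

    def test_low_contrast_voxel_rejected_regardless_of_neighborhood(self):
        vol, ctx, ifa = self._scene()
        vol.data[3, 4, 4] = -60.0  # C = 0.4 -> false branch
        assert not self._run(vol, ctx, ifa)[3, 4, 4]

    def test_tie_on_local_threshold_passes(self):
        vol, ctx, ifa = self._scene()
        # uniform -30 HU slab (C = 0.7): an interior slab voxel sees only
        # -30 HU neighbors, so SD26 = 0 and HU == mean26 - 2 SD26 exactly
        vol.data[3:6, :, :] = -30.0
        cand = self._run(vol, ctx, ifa)
        assert cand[4, 4, 4]

    def test_dermis_connected_blocked(self):
        vol, ctx, ifa = self._scene()
        vol.data[3, 4, 4] = 20.0
        cmap = contrast_map(vol, ctx)
        dermis = np.zeros(vol.shape, bool)
        dermis[3, 4, 4] = True
        cand, _ = find_candidate_voxels(vol, cmap, ifa, dermis)
        assert not cand[3, 4, 4]


class TestRayShielding:
    def _arena(self, n_candidates):
        shape = (13, 13, 13)
        center = (6, 6, 6)
        cand = np.zeros(shape, bool)
        for d in DIRECTIONS26[:n_candidates]:
            cand[tuple(np.add(center, d))] = True
        ifa = np.zeros(shape, bool)
        band = np.ones(shape, bool)
        return ifa, cand, band, center

    def test_fully_enclosed_voxel_reflects_all_rays(self):
        ifa, cand, band, center = self._arena(26)
        res = ray_shielding(ifa, cand, band, center)
        assert res.reflect_counts[center] == 26
        assert res.status[center] == SHIELDED

    def test_quorum_boundary_17_vs_16(self):
        for n, status_ok in [(17, True), (16, False)]:
            ifa, cand, band, center = self._arena(n)
            res = ray_shielding(ifa, cand, band, center)
            assert res.reflect_counts[center] == n
            assert bool(res.status[center] == SHIELDED) == status_ok

    def test_open_half_space_not_shielded(self):
        shape = (31, 31, 31)
        ifa = np.zeros(shape, bool)
        ifa[:, :, :14] = True  # solid floor; everything above is open
        band = np.ones(shape, bool)
        cand = np.zeros(shape, bool)
        center = (15, 15, 15)
        res = ray_shielding(ifa, cand, band, center)
        assert res.reflect_counts[center] <= 13
        assert res.status[center] == NOT_SHIELDED

    def test_seed_on_solid_rejected(self):
        ifa, cand, band, center = self._arena(26)
        with pytest.raises(ValueError, match="seed"):
            ray_shielding(ifa, cand, band, tuple(np.add(center, DIRECTIONS26[0])))

    def test_shielded_monotone_in_candidates(self):
        ifa, cand, band, center = self._arena(20)
        res_small = ray_shielding(ifa, cand[:, :, :] & False, band, center)
        res_big = ray_shielding(ifa, cand, band, center)
        assert res_big.reflect_counts[center] >= res_small.reflect_counts[center]


class TestFinalize:
    def test_no_candidates_no_seeds_is_smoothed_ifa(self):
        ifa = np.zeros((20, 20, 20), bool)
        ifa[4:16, 4:16, 4:16] = True
        out, surface = finalize_if(ifa, np.zeros_like(ifa))
        # smoothing of a solid convex block: nothing added, only the sharp
        # edge/corner voxels may be rounded off
        assert not (out & ~ifa).any()
        core = ndimage.binary_erosion(ifa, iterations=2)
        assert not (core & ~out).any()
        assert surface.sum() > 0 and not (surface & ~out).any()

    def test_porous_unselected_cluster_removed_by_smoothing(self):
        ifa = np.zeros((30, 20, 20), bool)
        ifa[2:10, 4:16, 4:16] = True
        cand = np.zeros_like(ifa)
        cand[20, 4:16, 4:16] = True  # 1-voxel-thick floating plate
        out, _ = finalize_if(ifa, cand)
        assert not out[20, :, :].any()

    def test_reject_marker_removes_conglomerate(self):
        ifa = np.zeros((30, 20, 20), bool)
        ifa[2:10, 4:16, 4:16] = True
        cand = np.zeros_like(ifa)
        cand[10:14, 4:16, 4:16] = True  # solid attached slab
        kept, _ = finalize_if(ifa, cand)
        rejected, _ = finalize_if(ifa, cand, reject_markers=[(12, 10, 10)])
        assert kept[12, 10, 10]
        assert not rejected[12, 10, 10]


def test_dermis_connected_requires_surface_path():
    body = np.zeros((20, 12, 8), bool)
    body[2:18, 2:10, :] = True
    c = np.zeros((20, 12, 8))
    c[2, 2:10, :] = 1.5        # surface-touching high-contrast sheet
    c[10, 5, 4] = 1.5          # isolated interior blob
    dermis = dermis_connected_mask(c, body)
    assert dermis[2, 5, 4]
    assert not dermis[10, 5, 4]
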