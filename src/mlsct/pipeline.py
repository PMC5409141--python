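"""End-to-end orchestration: analysis VOI -> calibration -> fascia ->
compartments -> features, driven by a replayable session.

A :class:`Session` captures every operator input (muscle grade, slab
landmarks, gap seeds, reject markers, water value source, config overrides),
so any segmentation can be replayed non-interactively and bit-identically —
the foundation of the reanalysis-precision design.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from . import analysis_voi as av
from . import calibration as cal
from . import compartments as cmp
from . import fascia as fs
from .config import AnalysisConfig
from .features import (
    FeatureTable,
    density,
    fractal_dimension,
    gmm_density,
    granulometry_avg,
    relative_volume,
    sphericity,
)
from .volume import CTVolume, VoxelMask

log = logging.getLogger("mlsct")

__all__ = [
    "Session",
    "SegmentationBundle",
    "run_segment",
    "replay_compartments",
    "run_features",
    "FEATURE_ROSTER",
]


@dataclass
class Session:
    """All operator inputs of one analysis; fully determines the outputs."""

    grade: int = 1
    proximal_slice: int = 0
    n_slices: int | None = None        # explicit slab height, or None to derive
    trochanter_slice: int | None = None  # needed when n_slices is None
    gap_seeds: list = field(default_factory=list)
    reject_markers: list = field(default_factory=list)
    ct_h2o: float | None = None        # explicit water value; else insert ROI
    sphere_center: list | None = None  # manual surface-sphere placement
    config: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "Session":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class SegmentationBundle:
    """Masks and models produced by one segmentation run."""

    body: VoxelMask
    voi_us: VoxelMask
    voi_at: VoxelMask
    voi_ifa: VoxelMask
    candidates: VoxelMask
    voi_if: VoxelMask
    fascia: VoxelMask
    dermis: VoxelMask
    voi_sat: VoxelMask
    voi_pat: VoxelMask
    voi_m: VoxelMask
    voi_mt: VoxelMask
    voi_mls: VoxelMask
    ctx: cal.CalibrationContext
    gmm_mls: cmp.GMMFit
    concentration: cmp.ConcentrationMap
    shielding: list
    cfg: AnalysisConfig
    femur: VoxelMask

    def masks(self) -> dict[str, VoxelMask]:
        out = {
            "body": self.body,
            "VOI_US": self.voi_us,
            "VOI_AT": self.voi_at,
            "VOI_IFA": self.voi_ifa,
            "candidates": self.candidates,
            "VOI_IF": self.voi_if,
            "fascia": self.fascia,
            "VOI_SAT": self.voi_sat,
            "VOI_PAT": self.voi_pat,
            "VOI_M": self.voi_m,
            "VOI_MT": self.voi_mt,
            "VOI_MLS": self.voi_mls,
        }
        sp = self.voi_if.spacing
        out["VOI_HDM"] = self.concentration.mask("B6", sp)
        out["VOI_IMAT"] = self.concentration.mask("IMAT", sp)
        return out


def _lateral_boundary(mask: np.ndarray) -> np.ndarray:
    """Surface of a slab-restricted volume, excluding the slab end faces.

    The analysis slab cuts anatomy at its proximal/distal ends; those cut
    faces are not fascia.  The occupied slice range is replicate-extended
    along z before erosion so only lateral surfaces count as boundary.
    """
    occ = np.nonzero(mask.any(axis=(0, 1)))[0]
    if len(occ) == 0:
        return mask.copy()
    k0, k1 = occ[0], occ[-1] + 1
    sub = mask[:, :, k0:k1]
    ext = np.concatenate([sub[:, :, :1], sub, sub[:, :, -1:]], axis=2)
    er = ndimage.binary_erosion(ext, border_value=1)[:, :, 1:-1]
    out = np.zeros_like(mask)
    out[:, :, k0:k1] = sub & ~er
    return out


def _stage(name):
    class _Ctx:
        def __enter__(self):
            log.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_segment(
    vol: CTVolume,
    femur_mask: VoxelMask,
    session: Session,
    water_roi: VoxelMask | None = None,
) -> SegmentationBundle:
    """Execute the full hierarchical segmentation for one session.

    ``water_roi`` is an ROI over the in-scan calibration insert; it supplies
    CT_H2O unless the session or config states an explicit value.
    """
    if femur_mask is None or not femur_mask.data.any():
        raise ValueError("a femoral bone mask is required before any computation")
    vol.check_mask(femur_mask)
    cfg = AnalysisConfig.from_dict(session.config) if session.config else AnalysisConfig()

    with _stage("thigh surface"):
        body, roi = av.segment_thigh_surface(vol, cfg, sphere_center=session.sphere_center)

    with _stage("calibration references"):
        if session.ct_h2o is not None:
            ct_h2o = float(session.ct_h2o)
        elif cfg.ct_h2o is not None:
            ct_h2o = float(cfg.ct_h2o)
        elif water_roi is not None:
            ct_h2o = float(vol.data[water_roi.data].mean())
        else:
            raise ValueError("CT_H2O unavailable: give a session/config value or insert ROI")
        ct_at, voi_at = cal.estimate_ct_at(vol, roi.mask, cfg)
        ctx = cal.CalibrationContext(
            ct_h2o=ct_h2o, ct_at=ct_at, hdm_constant=cfg.hdm_constant_hu,
            n_voi_at=voi_at.count(),
        )

    with _stage("analysis slab"):
        if session.n_slices is not None:
            n = int(session.n_slices)
        else:
            if session.trochanter_slice is None:
                raise ValueError("need n_slices or a trochanter landmark slice")
            frame = av.compute_anatomic_frame(
                femur_mask, session.trochanter_slice, vol.spacing[2]
            )
            n = frame.n_slices
        voi_us = av.define_voi_us(body, n, session.proximal_slice)

    with _stage("fascia: potential muscle"):
        cmap = cal.contrast_map(vol, ctx)
        gp = fs.grade_params(session.grade)
        alpha = fs.aggregation_map(cmap, gp.c_min, body.data)
        depth = ndimage.distance_transform_edt(body.data)
        potential = fs.classify_potential_muscle(
            cmap, alpha, gp, femur_mask.data, body.data,
            depth_vox=depth, min_depth=cfg.muscle_min_depth_vox,
            femur_dilation=cfg.femur_dilation_vox,
        )
        potential &= voi_us.data
        legs = fs.select_leg_components(potential, femur_mask.data)

    with _stage("fascia: compactification"):
        ifa = np.zeros(vol.shape, dtype=bool)
        for side, comp in legs.items():
            ifa |= fs.compactify(comp, cfg)
        ifa &= voi_us.data

    with _stage("fascia: candidates and shielding"):
        dermis = fs.dermis_connected_mask(cmap, body.data)
        candidates, band = fs.find_candidate_voxels(vol, cmap, ifa, dermis, cfg)
        shielding = []
        tested = np.zeros(vol.shape, dtype=bool)
        for seed in session.gap_seeds:
            seed = tuple(int(c) for c in seed)
            if tested[seed]:
                continue  # this gap region was already processed by another seed
            try:
                res = fs.ray_shielding(ifa, candidates, band, seed, cfg)
            except ValueError as e:
                warnings.warn(f"gap seed {seed} skipped: {e}", stacklevel=2)
                continue
            shielding.append(res)
            tested |= res.status > 0
        voi_if_arr, _ = fs.finalize_if(
            ifa, candidates, shielding, session.reject_markers, cfg
        )
        voi_if_arr &= voi_us.data
        voi_if = VoxelMask.like(vol, voi_if_arr, "VOI_IF")
        fascia = VoxelMask.like(vol, _lateral_boundary(voi_if_arr), "fascia")

    with _stage("compartments"):
        parts = _compartment_stage(vol, voi_us, voi_if, fascia, dermis, femur_mask, ctx, cfg)

    return SegmentationBundle(
        body=body, voi_us=voi_us, voi_at=voi_at,
        voi_ifa=VoxelMask.like(vol, ifa, "VOI_IFA"),
        candidates=VoxelMask.like(vol, candidates, "candidates"),
        voi_if=voi_if, fascia=fascia,
        dermis=VoxelMask.like(vol, dermis, "dermis"),
        shielding=shielding, cfg=cfg, femur=femur_mask,
        **parts,
    )


def _compartment_stage(
    vol: CTVolume,
    voi_us: VoxelMask,
    voi_if: VoxelMask,
    fascia: VoxelMask,
    dermis: np.ndarray,
    femur_mask: VoxelMask,
    ctx: cal.CalibrationContext,
    cfg: AnalysisConfig,
) -> dict:
    """SAT/T_AT/PAT/M/GMM/MT/bins from a given fascia-level segmentation.

    Everything here is derived from HU histograms and set algebra on the
    supplied masks, so the stage can be replayed on a different (e.g.
    noise-augmented) volume while the fascia-level segmentation is held.
    """
    voi_sat = cmp.segment_sat(voi_us, voi_if, dermis)
    t_at, sat_star = cal.compute_t_at(vol, voi_sat, cfg)
    ctx.t_at = t_at
    ctx.sat_star = sat_star
    ctx.validate()
    voi_pat, voi_m = cmp.segment_pat_and_m(
        vol, voi_if, fascia.data, t_at, femur_mask, cfg.femur_dilation_vox
    )
    voi_mls = VoxelMask(voi_sat.data | voi_if.data, "VOI_MLS", vol.spacing)
    gmm = cmp.fit_gmm(vol, voi_mls, sat_star, ctx, cfg)
    voi_mt = cmp.segment_mt(vol, voi_if, gmm, femur_mask, cfg.femur_dilation_vox)
    conc = cmp.concentration_bins(vol, voi_if, ctx, femur_mask, cfg.femur_dilation_vox)
    return {
        "voi_sat": voi_sat, "voi_pat": voi_pat, "voi_m": voi_m,
        "voi_mt": voi_mt, "voi_mls": voi_mls, "ctx": ctx,
        "gmm_mls": gmm, "concentration": conc,
    }


def replay_compartments(vol: CTVolume, bundle: SegmentationBundle) -> SegmentationBundle:
    """Replay the histogram-derived stages on a new volume.

    The fascia-level segmentation (body, analysis slab, VOI_IF, fascia,
    dermis) and the calibration references CT_H2O / CT_AT are taken from the
    recorded bundle; the adipose threshold T_AT, the MLS Gaussian mixture and
    everything downstream (PAT/M, MT, concentration bins) are re-derived from
    the new volume's HU values.
    """
    cfg = bundle.cfg
    ctx = cal.CalibrationContext(
        ct_h2o=bundle.ctx.ct_h2o,
        ct_at=bundle.ctx.ct_at,
        hdm_constant=bundle.ctx.hdm_constant,
        n_voi_at=bundle.ctx.n_voi_at,
    )
    parts = _compartment_stage(
        vol, bundle.voi_us, bundle.voi_if, bundle.fascia,
        bundle.dermis.data, bundle.femur, ctx, cfg,
    )
    return SegmentationBundle(
        body=bundle.body, voi_us=bundle.voi_us, voi_at=bundle.voi_at,
        voi_ifa=bundle.voi_ifa, candidates=bundle.candidates,
        voi_if=bundle.voi_if, fascia=bundle.fascia, dermis=bundle.dermis,
        shielding=bundle.shielding, cfg=cfg, femur=bundle.femur,
        **parts,
    )


#: the feature x VOI applicability roster
FEATURE_ROSTER: dict[str, tuple[str, ...]] = {
    "D": ("SAT", "IF", "M", "MT", "HDM", "IMAT"),
    "D_IF_GMM": ("MT",),
    "D_MLS_GMM": ("MT",),
    "rV_IF": ("M", "MT", "HDM", "IMAT"),
    "rV_MLS": ("SAT", "IF"),
    "G_avg": ("MT", "HDM", "IMAT"),
    "FD": ("IF", "M", "MT"),
    "Psi": ("M", "MT"),
}

_UNITS = {"D": "HU", "D_IF_GMM": "HU", "D_MLS_GMM": "HU", "G_avg": "mm"}


def run_features(
    bundle: SegmentationBundle, vol: CTVolume, ctx: cal.CalibrationContext | None = None
) -> FeatureTable:
    """Compute the full feature roster on a segmentation bundle.

    A missing or failing (VOI, feature) cell is recorded as NaN rather than
    aborting.  ``ctx`` defaults to the bundle's calibration; passing a shifted
    context supports calibration-sensitivity studies.
    """
    ctx = ctx or bundle.ctx
    cfg = bundle.cfg
    masks = bundle.masks()
    vois = {
        "SAT": masks["VOI_SAT"], "IF": masks["VOI_IF"], "M": masks["VOI_M"],
        "MT": masks["VOI_MT"], "HDM": masks["VOI_HDM"], "IMAT": masks["VOI_IMAT"],
    }
    table = FeatureTable(ctx=ctx, config=cfg.to_dict())

    gmm_if = None
    try:
        gmm_if = cmp.fit_gmm(vol, bundle.voi_if, ctx.sat_star, ctx, cfg)
    except Exception as e:  # noqa: BLE001 - recorded as missing below
        warnings.warn(f"GMM fit on VOI_IF failed: {e}", stacklevel=2)

    def compute(feature: str, voi_name: str):
        voi = vois[voi_name]
        if feature == "D":
            return density(vol, voi, ctx)
        if feature == "D_IF_GMM":
            return gmm_density(gmm_if, "MT", ctx) if gmm_if is not None else np.nan
        if feature == "D_MLS_GMM":
            return gmm_density(bundle.gmm_mls, "MT", ctx)
        if feature == "rV_IF":
            return relative_volume(voi, vois["IF"])
        if feature == "rV_MLS":
            return relative_volume(voi, bundle.voi_mls)
        if feature == "G_avg":
            return granulometry_avg(voi, vol.spacing, cfg.granulometry_step_mm)
        if feature == "FD":
            return fractal_dimension(voi, on_boundary=cfg.fd_on_boundary)
        if feature == "Psi":
            return sphericity(voi, vol.spacing)
        raise KeyError(feature)

    for feature, voi_names in FEATURE_ROSTER.items():
        for voi_name in voi_names:
            try:
                value = compute(feature, voi_name)
            except Exception as e:  # noqa: BLE001 - per-cell missing value
                warnings.warn(f"feature {feature}({voi_name}) missing: {e}", stacklevel=2)
                value = np.nan
            table.add(voi_name, feature, value, _UNITS.get(feature, ""))
    return table
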