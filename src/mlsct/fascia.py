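"""Hierarchical 3D segmentation of the intrafascial volume and the fascia.

The fascia is a thin, low-contrast sheet separating subcutaneous fat from the
intrafascial compartment, often bordered by fat on both sides.  Rather than
chasing the sheet directly, the method builds the intrafascial volume VOI_IF
from the inside out:

1. *Potential muscle*: voxels deep under the skin, femur-connected, with
   contrast C >= C_min and neighborhood aggregation alpha >= alpha_min, where
   C_min = 0.75 - 0.15 G and alpha_min = 0.85 - 0.05 G for an operator grade
   G in {1, 2, 3} (G = 3: moth-eaten / washed-out muscle).
2. *Compactification*: the two largest components (right/left leg) are closed
   with a z-elongated ellipsoidal element and contour-filled, giving VOI_IFA;
   its surface FA approximates the fascia.
3. *Refinement*: volume growing from FA with a local noise-adaptive threshold
   collects candidate voxels (fascia fragments and trapped tissue) within a
   15-voxel band; operator seed points in the fat gaps between FA and
   candidate clusters start a 26-direction ray-reflection test that marks gap
   voxels shielded when >= 65% of the rays reflect; shielded, filled and
   candidate voxels merge with VOI_IFA and a morphological smoothing removes
   porous debris.  The surface of the result is the fascia.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._morphology import (
    DIRECTIONS26,
    STRUCT26,
    ball_close,
    ball_open,
    boundary_voxels,
    ellipsoid_close,
    fill_holes_per_slice,
    label26,
    neighbor_mean_sd,
    neighbor_true_count,
)
from .config import AnalysisConfig, grade_in_range
from .volume import CTVolume

log = logging.getLogger("mlsct")

__all__ = [
    "GradeParams",
    "ShieldingResult",
    "grade_params",
    "aggregation_map",
    "classify_potential_muscle",
    "select_leg_components",
    "compactify",
    "dermis_connected_mask",
    "find_candidate_voxels",
    "ray_shielding",
    "finalize_if",
]

# shielding status codes
UNTESTED, NOT_SHIELDED, SHIELDED, FILLED = 0, 1, 2, 3


@dataclass(frozen=True)
class GradeParams:
    """Thresholds induced by the muscle-appearance grade G."""

    G: int
    c_min: float
    alpha_min: float


def grade_params(G: int) -> GradeParams:
    """C_min = 0.75 - 0.15 G and alpha_min = 0.85 - 0.05 G, G in {1, 2, 3}."""
    G = grade_in_range(G)
    return GradeParams(G=G, c_min=0.75 - 0.15 * G, alpha_min=0.85 - 0.05 * G)


def aggregation_map(
    cmap: np.ndarray, c_min: float, body_mask: np.ndarray | None = None
) -> np.ndarray:
    """Fraction of a voxel's 26 neighbors with contrast >= C_min.

    Neighbors outside the grid, or outside the body mask when one is given,
    count as failing.  Ties pass (Heaviside with theta(0) = 1).
    """
    passing = cmap >= c_min
    if body_mask is not None:
        passing = passing & body_mask
    return neighbor_true_count(passing) / 26.0


def classify_potential_muscle(
    cmap: np.ndarray,
    alpha: np.ndarray,
    gp: GradeParams,
    femur_mask: np.ndarray,
    body_mask: np.ndarray,
    depth_vox: np.ndarray | None = None,
    min_depth: float = 10.0,
    femur_dilation: int = 1,
) -> np.ndarray:
    """Apply the four potential-muscle conditions.

    (1) Euclidean depth from the body surface >= ``min_depth`` voxels;
    (2) membership in a contrast/aggregation component that touches the
    1-voxel-dilated femur; (3) C >= C_min; (4) alpha >= alpha_min.
    """
    if depth_vox is None:
        depth_vox = ndimage.distance_transform_edt(body_mask)
    surv34 = (cmap >= gp.c_min) & (alpha >= gp.alpha_min) & body_mask
    labels, _ = label26(surv34)
    fem = ndimage.binary_dilation(femur_mask, STRUCT26, iterations=max(femur_dilation, 1))
    connected = np.unique(labels[fem & surv34])
    connected = connected[connected > 0]
    kept = np.isin(labels, connected) & (depth_vox >= min_depth)
    if not kept.any():
        raise ValueError(
            "no potential-muscle voxels survive the four conditions; "
            "consider a higher muscle-appearance grade G"
        )
    return kept


def select_leg_components(
    mask: np.ndarray, femur_mask: np.ndarray
) -> dict[str, np.ndarray]:
    """Keep the two largest 26-components, labelled right/left by COM x.

    The component whose center of mass lies at lower x than the femur-mask
    center is called right (radiological convention: patient right on the
    image left).  A single-leg image returns one component with a warning.
    """
    labels, k = label26(mask)
    if k == 0:
        raise ValueError("no connected components to select legs from")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    order = np.argsort(counts)[::-1]
    keep = [lab for lab in order[:2] if counts[lab] > 0]
    fem_cx = ndimage.center_of_mass(femur_mask)[0] if femur_mask.any() else mask.shape[0] / 2
    out: dict[str, np.ndarray] = {}
    if len(keep) == 1:
        warnings.warn("single leg component found", stacklevel=2)
        comp = labels == keep[0]
        side = "right" if ndimage.center_of_mass(comp)[0] < fem_cx else "left"
        out[side] = comp
        return out
    comps = [labels == lab for lab in keep]
    cxs = [ndimage.center_of_mass(c)[0] for c in comps]
    ir = int(np.argmin(cxs))
    out["right"] = comps[ir]
    out["left"] = comps[1 - ir]
    return out


def compactify(component: np.ndarray, cfg: AnalysisConfig | None = None) -> np.ndarray:
    """Close with a z-elongated ellipsoid and contour-fill slice-wise.

    The elongation along z matches the cylindrical fascia and the axial run
    of the muscles; contour filling removes any remaining interior cavities
    (vessels, lipid inclusions).  The surface of the result is FA.
    """
    cfg = cfg or AnalysisConfig()
    if not component.any():
        raise ValueError("cannot compactify an empty component")
    closed = ellipsoid_close(component, cfg.closing_semiaxes_vox)
    return fill_holes_per_slice(closed)


def dermis_connected_mask(
    cmap: np.ndarray, body_mask: np.ndarray
) -> np.ndarray:
    """Voxels with C > 1 that are 26-connected to the thigh surface."""
    high = (cmap > 1.0) & body_mask
    labels, _ = label26(high)
    shell = boundary_voxels(body_mask)
    touching = np.unique(labels[shell & high])
    touching = touching[touching > 0]
    return np.isin(labels, touching)


def find_candidate_voxels(
    vol: CTVolume,
    cmap: np.ndarray,
    voi_ifa: np.ndarray,
    dermis_mask: np.ndarray,
    cfg: AnalysisConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow candidate voxels from the fascia approximation FA.

    A voxel joins if it lies within the 15-voxel Euclidean band around FA, is
    not dermis-connected, and satisfies the local noise-adaptive predicate f:
    accept outright when C > 1; for 0.5 <= C <= 1 accept when
    HU >= mean26 - 2 SD26 of its neighborhood; reject otherwise.  Ties pass.

    Returns (candidates, band) where ``band`` is the distance band used (also
    the horizon of the ray-reflection model).
    """
    cfg = cfg or AnalysisConfig()
    fa = boundary_voxels(voi_ifa)
    dist = ndimage.distance_transform_edt(~fa)
    band = dist <= cfg.candidate_band_vox

    mean26, sd26, _ = neighbor_mean_sd(vol.data)
    g_ok = vol.data >= mean26 - cfg.local_sd_factor * sd26
    f_ok = (cmap > 1.0) | (((cmap >= 0.5) & (cmap <= 1.0)) & g_ok)

    grow = (f_ok & band & ~dermis_mask & ~voi_ifa) | fa
    labels, _ = label26(grow)
    seeded = np.unique(labels[fa])
    seeded = seeded[seeded > 0]
    candidates = np.isin(labels, seeded) & ~voi_ifa
    return candidates, band


@dataclass
class ShieldingResult:
    """Outcome of one seeded ray-reflection pass.

    ``status`` codes: 0 untested, 1 not-shielded, 2 shielded, 3 contour-filled.
    ``reflect_counts`` holds, for tested voxels, how many of the 26 rays
    reflected off a candidate or an intrafascia voxel.
    """

    status: np.ndarray
    reflect_counts: np.ndarray
    seed: tuple[int, int, int]
    quorum: int = 17

    @property
    def shielded(self) -> np.ndarray:
        return self.status == SHIELDED

    @property
    def filled(self) -> np.ndarray:
        return self.status == FILLED

    def __post_init__(self) -> None:
        tested = self.status == SHIELDED
        if tested.any() and self.reflect_counts[tested].min() < self.quorum:
            raise ValueError("shielded voxel with reflections below the quorum")


def ray_shielding(
    voi_ifa: np.ndarray,
    candidates: np.ndarray,
    band: np.ndarray,
    seed: tuple[int, int, int],
    cfg: AnalysisConfig | None = None,
) -> ShieldingResult:
    """Test the fat gap reachable from ``seed`` with the 26-ray reflection model.

    The gap is region-grown from the seed through voxels that are neither
    intrafascia-approximation nor candidate, inside the candidate band.  Every
    gap voxel casts rays along the 26 integer lattice directions with unit
    voxel steps; a ray reflects when it hits a candidate or VOI_IFA voxel
    before travelling 15 voxels or leaving the band.  A voxel is shielded when
    at least ceil(0.65 * 26) = 17 rays reflect.  Gap voxels left unshielded
    but enclosed in-plane by the merged structure are contour-filled.
    """
    cfg = cfg or AnalysisConfig()
    seed = tuple(int(c) for c in seed)
    shape = voi_ifa.shape
    if voi_ifa[seed] or candidates[seed]:
        raise ValueError(
            f"seed {seed} lies inside the fascia approximation or on a candidate; "
            "it must be placed in the gap between them"
        )
    gap = band & ~voi_ifa & ~candidates
    if not gap[seed]:
        raise ValueError(f"seed {seed} lies outside the testable gap band")
    labels, _ = label26(gap)
    region = labels == labels[seed]
    idx = np.argwhere(region)
    solid = voi_ifa | candidates
    horizon = int(np.floor(cfg.candidate_band_vox))

    counts = np.zeros(len(idx), dtype=np.int16)
    for d in DIRECTIONS26:
        active = np.ones(len(idx), dtype=bool)
        reflected = np.zeros(len(idx), dtype=bool)
        for step in range(1, horizon + 1):
            if not active.any():
                break
            pos = idx[active] + step * d
            ok = np.all((pos >= 0) & (pos < np.array(shape)), axis=1)
            act_idx = np.nonzero(active)[0]
            # rays leaving the grid die unreflected
            active[act_idx[~ok]] = False
            pos = pos[ok]
            act_idx = act_idx[ok]
            t = tuple(pos.T)
            hit = solid[t]
            reflected[act_idx[hit]] = True
            active[act_idx[hit]] = False
            # rays leaving the band die unreflected
            out_band = ~band[t] & ~hit
            active[act_idx[out_band]] = False
        counts += reflected

    status = np.zeros(shape, dtype=np.int8)
    quorum = cfg.shielding_quorum
    sh = counts >= quorum
    status[tuple(idx[sh].T)] = SHIELDED
    status[tuple(idx[~sh].T)] = NOT_SHIELDED

    # contour filling of enclosed leftovers (status h)
    merged = solid | (status == SHIELDED)
    filled = fill_holes_per_slice(merged) & ~merged
    fill_sel = filled & region & (status != SHIELDED)
    status[fill_sel] = FILLED

    rc = np.zeros(shape, dtype=np.int16)
    rc[tuple(idx.T)] = counts
    return ShieldingResult(status=status, reflect_counts=rc, seed=seed, quorum=quorum)


def finalize_if(
    voi_ifa: np.ndarray,
    candidates: np.ndarray,
    shielding: list[ShieldingResult] = (),
    reject_markers: list[tuple[int, int, int]] = (),
    cfg: AnalysisConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge, reject, smooth: the final VOI_IF and its fascia surface.

    Candidate conglomerates marked by operator reject markers are removed
    before merging.  Smoothing is a morphological opening followed by closing
    with a 2-voxel-radius ball, removing porous unselected debris.
    Returns (voi_if, fascia_surface); warns if a leg fragments.
    """
    cfg = cfg or AnalysisConfig()
    cand = candidates.copy()
    if len(reject_markers):
        labels, _ = label26(candidates)
        for m in reject_markers:
            m = tuple(int(c) for c in m)
            lab = labels[m]
            if lab > 0:
                cand &= labels != lab
            else:
                warnings.warn(f"reject marker {m} is not on a candidate voxel", stacklevel=2)
    merged = voi_ifa | cand
    for res in shielding:
        merged |= res.shielded | res.filled
    voi_if = ball_close(ball_open(merged, cfg.smoothing_radius_vox), cfg.smoothing_radius_vox)

    _, ncomp = label26(voi_if)
    if ncomp > 2:
        sizes = np.bincount(label26(voi_if)[0].ravel())[1:]
        warnings.warn(
            f"VOI_IF fragments into {ncomp} components (sizes {sorted(sizes)[::-1][:5]})",
            stacklevel=2,
        )
    return voi_if, boundary_voxels(voi_if)
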