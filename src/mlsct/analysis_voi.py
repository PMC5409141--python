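"""Thigh surface segmentation and the anatomy-scaled analysis slab VOI_US.

The analysis slab is anchored to femoral landmarks so its position and height
scale with subject anatomy: a plane A through the femur center of mass at the
lesser-trochanter mid-height, perpendicular to the shaft axis; the femoral
head apex P2 maximally distant from A; their separation projected onto the
scanner z-axis gives the anatomic distance d, and the slab holds
n = floor(0.5 * d / s) slices (s: slice thickness), extending distally from
the distal end of the acetabulum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._morphology import largest_components
from .config import AnalysisConfig
from .volume import CTVolume, VoxelMask

__all__ = [
    "AnatomicFrame",
    "SurfaceROI",
    "segment_thigh_surface",
    "compute_anatomic_frame",
    "define_voi_us",
]


@dataclass
class SurfaceROI:
    """Spherical ROI straddling the skin, used for thresholds and AT growing."""

    center: tuple[int, int, int]
    radius_vox: int
    mask: VoxelMask
    threshold_hu: float         # T_surf derived from the sphere spectrum


@dataclass
class AnatomicFrame:
    """Femur-derived coordinate frame of the analysis slab."""

    plane_point: np.ndarray     # mm, on the shaft axis at trochanter mid-height
    plane_normal: np.ndarray    # unit vector along the femoral shaft axis
    apex: np.ndarray            # P2, femoral-head voxel farthest from plane A (mm)
    d_mm: float                 # |z-projection of (P2 - plane_point)|
    n_slices: int               # floor(0.5 * d / s), at least 1

    def __post_init__(self) -> None:
        if self.d_mm <= 0:
            raise ValueError(f"anatomic distance d must be > 0, got {self.d_mm}")
        if self.n_slices < 1:
            raise ValueError("slab must contain at least one slice")


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius**2


def _place_surface_sphere(vol: CTVolume, radius: int) -> tuple[int, int, int]:
    """First air-to-tissue crossing along a lateral ray toward the body.

    The ray starts at the i=0 image border, at the (j, k) position of the
    densest-tissue centroid (a proxy for the femur centroid), and advances in
    +i until HU rises above the air/tissue midpoint.
    """
    dense = vol.data > 200.0  # bone-range voxels
    if dense.any():
        _, j0, k0 = (int(round(c)) for c in ndimage.center_of_mass(dense))
    else:
        j0, k0 = vol.shape[1] // 2, vol.shape[2] // 2
    profile = vol.data[:, j0, k0]
    crossing = np.nonzero(profile > -500.0)[0]
    if len(crossing) == 0 or profile[0] > -500.0:
        raise ValueError(
            "no air-to-tissue crossing found along the lateral ray; "
            "place the surface sphere manually"
        )
    return int(crossing[0]), j0, k0


def segment_thigh_surface(
    vol: CTVolume, cfg: AnalysisConfig | None = None, sphere_center=None
) -> tuple[VoxelMask, SurfaceROI]:
    """Segment the body from the air background.

    A sphere (default radius 10 voxels) straddles the skin; the threshold is
    the 70% point between the lowest and highest HU inside the sphere.  The
    body mask is the largest 3D connected component above the threshold,
    cavity-filled.
    """
    cfg = cfg or AnalysisConfig()
    r = cfg.surface_sphere_radius_vox
    center = tuple(sphere_center) if sphere_center is not None else _place_surface_sphere(vol, r)
    sphere = _sphere_mask(vol.shape, center, r)
    spec = vol.data[sphere]
    t_surf = float(spec.min() + cfg.surface_threshold_fraction * (spec.max() - spec.min()))
    above = vol.data > t_surf
    comps = largest_components(above, 1)
    if not comps:
        raise ValueError("no voxels above the surface threshold; volume may be all air")
    body = ndimage.binary_fill_holes(comps[0])
    roi = SurfaceROI(
        center=center,
        radius_vox=r,
        mask=VoxelMask.like(vol, sphere, "surface_sphere"),
        threshold_hu=t_surf,
    )
    return VoxelMask.like(vol, body, "body"), roi


def compute_anatomic_frame(
    femur_mask: VoxelMask,
    trochanter_slice: int,
    slice_thickness_mm: float,
    spacing=None,
) -> AnatomicFrame:
    """Build the slab frame from the femur mask and the operator landmark.

    The shaft axis is the principal axis of the femur mask; plane A passes
    through the femur center of mass in the given slice.  P2 is the femur
    voxel with maximal signed distance from A on the head side.
    """
    sp = np.asarray(spacing if spacing is not None else femur_mask.spacing, float)
    pts = np.argwhere(femur_mask.data)
    if len(pts) < 100:
        raise ValueError(f"degenerate femur mask ({len(pts)} voxels; need >= 100)")
    xyz = pts * sp

    in_slice = pts[:, 2] == int(trochanter_slice)
    if not in_slice.any():
        raise ValueError(f"femur mask empty in trochanter slice {trochanter_slice}")
    plane_point = xyz[in_slice].mean(axis=0)

    centered = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    axis = axis / np.linalg.norm(axis)

    signed = (xyz - plane_point) @ axis
    # the head side is where the mask extends farther from plane A
    if abs(signed.min()) > abs(signed.max()):
        axis = -axis
        signed = -signed
    apex = xyz[int(np.argmax(signed))]

    d = float(abs((apex - plane_point)[2]))
    if d <= 0:
        raise ValueError("anatomic distance d collapsed to zero (femur axis in-plane?)")
    n = max(1, int(np.floor(0.5 * d / float(slice_thickness_mm))))
    return AnatomicFrame(
        plane_point=plane_point, plane_normal=axis, apex=apex, d_mm=d, n_slices=n
    )


def define_voi_us(
    body_mask: VoxelMask, n_slices: int, proximal_slice: int, name: str = "VOI_US"
) -> VoxelMask:
    """Restrict the body mask to ``n_slices`` contiguous slices.

    The slab extends distally (toward higher k) from ``proximal_slice``, the
    distal end of the acetabulum.  A slab reaching past the grid is clipped
    with a warning.
    """
    nz = body_mask.shape[2]
    if not (0 <= proximal_slice < nz):
        raise ValueError(f"proximal slice {proximal_slice} outside grid of {nz} slices")
    stop = proximal_slice + int(n_slices)
    if stop > nz:
        warnings.warn(
            f"analysis slab [{proximal_slice}, {stop}) exceeds the grid; clipped to {nz}",
            stacklevel=2,
        )
        stop = nz
    out = np.zeros_like(body_mask.data)
    out[:, :, proximal_slice:stop] = body_mask.data[:, :, proximal_slice:stop]
    return VoxelMask(out, name, body_mask.spacing)
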