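"""Volumes, masks and seed sets with one fixed coordinate convention.

Arrays are indexed ``(i, j, k)`` with 0-based voxel indices and the scanner
slice axis as the **last** index ``k``.  Spacing is millimetres per voxel along
each axis.  Hounsfield values are stored as float32.  Masks are boolean grids
tied to the geometry of a reference volume; geometry consistency is asserted
whenever a mask is attached to or combined with a volume.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = [
    "CTVolume",
    "VoxelMask",
    "SeedSet",
    "GeometryError",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
]

#: plausible clinical HU range; values outside trigger a warning, not an error
HU_PLAUSIBLE = (-1100.0, 3100.0)


class GeometryError(ValueError):
    """A mask/volume pair does not share shape or spacing."""


@dataclass
class CTVolume:
    """A 3D scalar CT grid in Hounsfield units.

    Attributes
    ----------
    data : ndarray, float32, shape (nx, ny, nz)
        HU values; ``k`` (last axis) is the scanner slice axis.
    spacing : tuple of 3 floats
        mm per voxel along (i, j, k).
    origin : tuple of 3 floats
        Physical position (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HU grid contains non-finite values")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < HU_PLAUSIBLE[0] or hi > HU_PLAUSIBLE[1]:
            warnings.warn(
                f"HU range [{lo:.0f}, {hi:.0f}] outside plausible "
                f"[{HU_PLAUSIBLE[0]:.0f}, {HU_PLAUSIBLE[1]:.0f}]",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "CTVolume":
        return replace(self, data=np.asarray(data, dtype=np.float32))

    def check_mask(self, mask: "VoxelMask") -> None:
        if mask.data.shape != self.data.shape:
            raise GeometryError(
                f"mask '{mask.name}' shape {mask.data.shape} != volume shape {self.data.shape}"
            )
        if not np.allclose(mask.spacing, self.spacing):
            raise GeometryError(
                f"mask '{mask.name}' spacing {mask.spacing} != volume spacing {self.spacing}"
            )


@dataclass
class VoxelMask:
    """A named binary grid aligned to a :class:`CTVolume`."""

    data: np.ndarray
    name: str = "mask"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @classmethod
    def like(cls, vol: CTVolume, data: np.ndarray, name: str) -> "VoxelMask":
        m = cls(data=data, name=name, spacing=vol.spacing)
        vol.check_mask(m)
        return m

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.count() * float(np.prod(self.spacing))

    # -- set algebra (names combine for traceability) --
    def __or__(self, other: "VoxelMask") -> "VoxelMask":
        self._check(other)
        return VoxelMask(self.data | other.data, f"({self.name}|{other.name})", self.spacing)

    def __and__(self, other: "VoxelMask") -> "VoxelMask":
        self._check(other)
        return VoxelMask(self.data & other.data, f"({self.name}&{other.name})", self.spacing)

    def __sub__(self, other: "VoxelMask") -> "VoxelMask":
        self._check(other)
        return VoxelMask(self.data & ~other.data, f"({self.name}-{other.name})", self.spacing)

    def _check(self, other: "VoxelMask") -> None:
        if self.data.shape != other.data.shape or not np.allclose(self.spacing, other.spacing):
            raise GeometryError(
                f"masks '{self.name}' and '{other.name}' are on different grids"
            )


SEED_ROLES = ("fascia-gap", "reject-conglomerate")


@dataclass
class SeedSet:
    """Operator-placed voxel coordinates with a role.

    Roles: ``fascia-gap`` seeds start the ray-reflection shielding in the space
    between the fascia approximation and candidate voxels;
    ``reject-conglomerate`` markers exclude a candidate cluster from the final
    intrafascial volume.
    """

    seeds: list[tuple[int, int, int]] = field(default_factory=list)
    role: str = "fascia-gap"

    def __post_init__(self) -> None:
        if self.role not in SEED_ROLES:
            raise ValueError(f"role must be one of {SEED_ROLES}, got {self.role!r}")
        self.seeds = [tuple(int(c) for c in s) for s in self.seeds]

    def validate_in_grid(self, shape: tuple[int, int, int]) -> None:
        for s in self.seeds:
            if any(c < 0 or c >= n for c, n in zip(s, shape)):
                raise ValueError(f"seed {s} outside grid of shape {shape}")


# ---------------------------------------------------------------------------
# File IO.  SimpleITK handles NIfTI (.nii/.nii.gz), MetaImage (.mha/.mhd) and
# DICOM series directories; we transpose so the slice axis is last.
# ---------------------------------------------------------------------------

_WRITE_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


def _from_sitk(img: sitk.Image) -> CTVolume:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float32)
    return CTVolume(data=data, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def _to_sitk(vol: CTVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def read_volume(path: str) -> CTVolume:
    """Read a CT volume from NIfTI/MetaImage, or from a DICOM series directory.

    DICOM rescale slope/intercept are applied by the reader, so the returned
    grid is in HU.
    """
    if os.path.isdir(path):
        reader = sitk.ImageSeriesReader()
        ids = reader.GetGDCMSeriesIDs(path)
        if not ids:
            raise ValueError(f"no DICOM series found in directory {path!r}")
        files = reader.GetGDCMSeriesFileNames(path, ids[0])
        reader.SetFileNames(files)
        return _from_sitk(reader.Execute())
    if not any(path.endswith(e) for e in _WRITE_EXT + (".dcm",)):
        raise ValueError(f"unsupported volume format: {path!r}")
    return _from_sitk(sitk.ReadImage(path))


def write_volume(vol: CTVolume, path: str) -> None:
    if not any(path.endswith(e) for e in _WRITE_EXT):
        raise ValueError(f"unsupported output format: {path!r} (use {_WRITE_EXT})")
    sitk.WriteImage(_to_sitk(vol), path)


def write_mask(mask: VoxelMask, path: str) -> None:
    """Masks are stored as unsigned 8-bit label images."""
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(mask.data.transpose(2, 1, 0)).astype(np.uint8)
    )
    img.SetSpacing(mask.spacing)
    sitk.WriteImage(img, path)


def read_mask(path: str, name: str | None = None) -> VoxelMask:
    img = sitk.ReadImage(path)
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelMask(arr > 0, name or os.path.basename(path), tuple(img.GetSpacing()))
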