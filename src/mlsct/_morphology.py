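"""Shared discrete-geometry primitives.

Large-element binary morphology is done through Euclidean distance transforms:
dilation by a ball of radius r keeps every voxel within r of the set, erosion
keeps voxels deeper than r inside it.  For ellipsoidal elements the EDT is
computed with anisotropic sampling so the metric ball *is* the ellipsoid.
This is exact for the Euclidean ball/ellipsoid and orders of magnitude faster
than footprint convolution at clinical grid sizes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: 26-connectivity structure (3x3x3 cube)
STRUCT26 = np.ones((3, 3, 3), dtype=bool)

#: the 26 integer lattice directions (isotropic ray/neighbor set)
DIRECTIONS26 = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)

#: 3x3x3 kernel with the center removed — sums over the 26-neighborhood
KERNEL26 = np.ones((3, 3, 3), dtype=np.float64)
KERNEL26[1, 1, 1] = 0.0


def ball_dilate(mask: np.ndarray, radius: float, spacing=None) -> np.ndarray:
    """Dilate by a Euclidean ball of ``radius`` (same units as ``spacing``)."""
    if radius <= 0 or not mask.any():
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return d <= radius


def ball_erode(mask: np.ndarray, radius: float, spacing=None) -> np.ndarray:
    if radius <= 0 or not mask.any():
        return mask.copy()
    d = ndimage.distance_transform_edt(mask, sampling=spacing)
    return d > radius


def ball_close(mask: np.ndarray, radius: float, spacing=None) -> np.ndarray:
    return ball_erode(ball_dilate(mask, radius, spacing), radius, spacing)


def ball_open(mask: np.ndarray, radius: float, spacing=None) -> np.ndarray:
    return ball_dilate(ball_erode(mask, radius, spacing), radius, spacing)


def ellipsoid_close(mask: np.ndarray, semiaxes_vox) -> np.ndarray:
    """Morphological closing with an ellipsoidal element (semi-axes in voxels)."""
    a, b, c = (float(s) for s in semiaxes_vox)
    sampling = (1.0 / a, 1.0 / b, 1.0 / c)
    grown = ndimage.distance_transform_edt(~mask, sampling=sampling) <= 1.0
    return ndimage.distance_transform_edt(grown, sampling=sampling) > 1.0


def label26(mask: np.ndarray):
    """26-connected component labelling; returns (labels, n)."""
    return ndimage.label(mask, structure=STRUCT26)


def largest_components(mask: np.ndarray, n: int = 1) -> list[np.ndarray]:
    """The ``n`` largest 26-connected components, largest first."""
    labels, k = label26(mask)
    if k == 0:
        return []
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    order = np.argsort(counts)[::-1]
    return [labels == lab for lab in order[: min(n, k)] if counts[lab] > 0]


def fill_holes_per_slice(mask: np.ndarray) -> np.ndarray:
    """2D cavity filling applied slice-by-slice along the last (scanner) axis."""
    out = mask.copy()
    for k in range(mask.shape[2]):
        out[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k])
    return out


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Voxels of the set with at least one 6-neighbor outside it (its surface).

    Grid faces do not count as surface: anatomy continues beyond the scanned
    extent, so a voxel on the volume border is boundary only if an in-grid
    neighbor is outside the set.
    """
    return mask & ~ndimage.binary_erosion(mask, border_value=1)


def neighbor_sum(values: np.ndarray) -> np.ndarray:
    """Sum of each voxel's 26 neighbors (zero padding outside the grid)."""
    return ndimage.correlate(values.astype(np.float64), KERNEL26, mode="constant")


def neighbor_mean_sd(values: np.ndarray, support: np.ndarray | None = None):
    """Per-voxel mean and SD of the 26-neighborhood values.

    ``support`` restricts the statistic to neighbors inside a mask (voxels
    outside contribute nothing); near the grid edge the divisor is the actual
    in-grid neighbor count.
    """
    v = values.astype(np.float64)
    if support is None:
        w = np.ones_like(v)
    else:
        w = support.astype(np.float64)
        v = v * w
    cnt = ndimage.correlate(w, KERNEL26, mode="constant")
    s1 = ndimage.correlate(v, KERNEL26, mode="constant")
    s2 = ndimage.correlate(v * v, KERNEL26, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = s2 / cnt - mean**2
    mean = np.where(cnt > 0, mean, 0.0)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return mean, sd, cnt


def neighbor_true_count(mask: np.ndarray) -> np.ndarray:
    """Number of true 26-neighbors (out-of-grid neighbors count as false)."""
    return np.rint(
        ndimage.correlate(mask.astype(np.float64), KERNEL26, mode="constant")
    ).astype(np.int64)
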