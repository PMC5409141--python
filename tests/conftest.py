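"""Shared fixtures: small two-leg phantoms and segmented bundles.

The small phantom (160 x 96 x 24 voxels, 1 mm isotropic) exercises every
pipeline branch — two legs, fascia sheet, PAT pockets, EML speckles, edema
blobs, water insert — at a few seconds per segmentation.  Bundles are
session-scoped: tests treat them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from mlsct import PhantomSpec, Session, generate_thigh_phantom, run_segment
from mlsct._morphology import STRUCT26

SMALL = dict(
    grid_shape=(160, 96, 24),
    leg_radii_mm=(34.0, 32.0),
    sat_thickness_mm=8.0,
    femur_radius_mm=7.0,
    seed=2,
)
SLAB = (2, 22)  # proximal slice, stop


def make_phantom(**over):
    kw = dict(SMALL)
    kw.update(over)
    return generate_thigh_phantom(PhantomSpec(**kw))


def make_session(gt, ct_h2o=None):
    return Session(
        grade=1,
        proximal_slice=SLAB[0],
        n_slices=SLAB[1] - SLAB[0],
        gap_seeds=gt.gap_seeds,
        ct_h2o=ct_h2o,
    )


def slab_restrict(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    out[:, :, SLAB[0] : SLAB[1]] = mask[:, :, SLAB[0] : SLAB[1]]
    return out


def dilated_femur(gt) -> np.ndarray:
    return ndimage.binary_dilation(gt.mask("femur").data, STRUCT26)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def phantom_noisy():
    return make_phantom(noise_sd=10.0)


@pytest.fixture(scope="session")
def phantom_noiseless():
    return make_phantom(noise_sd=0.0)


def segment(vol, gt):
    sess = make_session(gt)
    with np.errstate(all="ignore"):
        return run_segment(vol, gt.mask("femur"), sess, water_roi=gt.mask("water"))


@pytest.fixture(scope="session")
def bundle_noisy(phantom_noisy):
    vol, gt = phantom_noisy
    return segment(vol, gt)


@pytest.fixture(scope="session")
def bundle_noiseless(phantom_noiseless):
    vol, gt = phantom_noiseless
    return segment(vol, gt)
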