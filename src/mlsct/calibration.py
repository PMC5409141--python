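"""Subject-specific HU calibration and the adipose/water contrast scale.

Two reference values anchor every density-dependent step: the subject's own
subcutaneous adipose tissue value CT_AT (mean HU of a region grown in the
adipose HU range from the surface sphere) and the water value CT_H2O from an
in-scan calibration insert.  They induce a linear contrast C with C = 0 at
CT_AT and C = 1 at CT_H2O.  The adipose threshold T_AT is the mean + 2 SD of
the trimmed, symmetrized SAT spectrum (SAT*), and the 100%-muscle threshold is
T_HDM = 35 HU + CT_H2O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._morphology import label26
from .config import AnalysisConfig
from .volume import CTVolume, VoxelMask

__all__ = [
    "CalibrationContext",
    "TrimmedHistogram",
    "estimate_ct_at",
    "contrast_map",
    "compute_t_at",
    "compute_t_hdm",
]


@dataclass
class TrimmedHistogram:
    """A 1-HU-bin histogram after the 30%-of-mode tail trim.

    ``sym_mean``/``sym_sd`` are moments of SAT*: the spectrum obtained by
    discarding bins below the mode and mirroring the upper half about it.
    """

    bin_centers: np.ndarray     # integer HU values
    counts: np.ndarray
    mode_hu: float
    mode_count: float
    trim_bounds: tuple[float, float]
    sym_mean: float
    sym_sd: float

    @property
    def peak_height(self) -> float:
        return self.mode_count


@dataclass
class CalibrationContext:
    """All subject-specific reference values of one analysis."""

    ct_h2o: float
    ct_at: float
    hdm_constant: float = 35.0
    t_at: float | None = None
    t_hdm: float = field(init=False)
    n_voi_at: int = 0           # voxel count of the grown adipose reference VOI
    sat_star: TrimmedHistogram | None = None

    def __post_init__(self) -> None:
        self.t_hdm = compute_t_hdm(self.ct_h2o, self.hdm_constant)

    def validate(self) -> "CalibrationContext":
        if not (self.ct_at < self.ct_h2o < self.t_hdm):
            raise ValueError(
                f"calibration ordering violated: CT_AT={self.ct_at:.1f} < "
                f"CT_H2O={self.ct_h2o:.1f} < T_HDM={self.t_hdm:.1f} required"
            )
        if self.t_at is not None and not (self.t_at < self.t_hdm):
            raise ValueError("T_AT must lie below T_HDM")
        return self

    def shifted_h2o(self, delta: float) -> "CalibrationContext":
        """Context with CT_H2O shifted by ``delta`` HU (calibration studies)."""
        ctx = CalibrationContext(
            ct_h2o=self.ct_h2o + delta,
            ct_at=self.ct_at,
            hdm_constant=self.hdm_constant,
            t_at=self.t_at,
            n_voi_at=self.n_voi_at,
            sat_star=self.sat_star,
        )
        return ctx

    def to_dict(self) -> dict:
        return {
            "ct_h2o": self.ct_h2o,
            "ct_at": self.ct_at,
            "t_at": self.t_at,
            "t_hdm": self.t_hdm,
            "hdm_constant": self.hdm_constant,
            "n_voi_at": self.n_voi_at,
        }


def compute_t_hdm(ct_h2o: float, constant: float = 35.0) -> float:
    """100%-muscle threshold: a fixed muscle constant re-anchored to water."""
    return float(constant + ct_h2o)


def estimate_ct_at(
    vol: CTVolume, sphere: VoxelMask, cfg: AnalysisConfig | None = None
) -> tuple[float, VoxelMask]:
    """Grow the adipose reference VOI from the surface sphere; return its mean.

    26-connected volume growing restricted to the adipose HU range (default
    [-190, -30]); the grown region must reach ``at_min_region_voxels`` or the
    sphere is assumed misplaced.
    """
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.at_growing_range_hu
    in_range = (vol.data >= lo) & (vol.data <= hi)
    labels, _ = label26(in_range)
    touched = np.unique(labels[sphere.data & in_range])
    touched = touched[touched > 0]
    voi = np.isin(labels, touched) if len(touched) else np.zeros(vol.shape, bool)
    n = int(voi.sum())
    if n < cfg.at_min_region_voxels:
        raise ValueError(
            f"adipose reference region has {n} voxels "
            f"(< {cfg.at_min_region_voxels}); surface sphere likely misplaced"
        )
    ct_at = float(vol.data[voi].mean())
    return ct_at, VoxelMask.like(vol, voi, "VOI_AT")


def contrast_map(vol: CTVolume, ctx: CalibrationContext) -> np.ndarray:
    """Linear contrast C: 0 at CT_AT, 1 at CT_H2O; unclamped.

    Values above 1 flag dermis/vessel/bone-like voxels, values below 0 flag
    leaner-than-reference fat.
    """
    denom = ctx.ct_h2o - ctx.ct_at
    if denom == 0:
        raise ValueError("CT_H2O equals CT_AT; contrast scale undefined")
    return (vol.data.astype(np.float64) - ctx.ct_at) / denom


def _histogram_1hu(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.rint(values).astype(np.int64)
    lo, hi = int(v.min()), int(v.max())
    counts = np.bincount(v - lo, minlength=hi - lo + 1).astype(np.float64)
    centers = np.arange(lo, hi + 1, dtype=np.float64)
    return centers, counts


def compute_t_at(
    vol: CTVolume, sat_mask: VoxelMask, cfg: AnalysisConfig | None = None
) -> tuple[float, TrimmedHistogram]:
    """Adipose threshold from the trimmed, symmetrized SAT spectrum.

    1-HU-bin histogram of the SAT VOI; both tails are cut from the outside in
    while bin counts stay below 30% of the modal count (removing vessel/edema
    contamination); SAT* discards bins below the mode and mirrors the upper
    half about it; T_AT = mean(SAT*) + 2 * SD(SAT*).
    """
    cfg = cfg or AnalysisConfig()
    if not sat_mask.data.any():
        raise ValueError("SAT mask is empty")
    centers, counts = _histogram_1hu(vol.data[sat_mask.data])
    mode_idx = int(np.argmax(counts))
    thr = cfg.histogram_trim_fraction * counts[mode_idx]

    lo = 0
    while lo < mode_idx and counts[lo] < thr:
        lo += 1
    hi = len(counts) - 1
    while hi > mode_idx and counts[hi] < thr:
        hi -= 1
    centers, counts = centers[lo : hi + 1], counts[lo : hi + 1]
    mode_idx -= lo
    if len(centers) < 10:
        raise ValueError(
            f"only {len(centers)} bins survive the trim; SAT spectrum too narrow"
        )

    # SAT*: upper half mirrored about the mode
    up_c = centers[mode_idx:]
    up_n = counts[mode_idx:]
    sym_c = np.concatenate([2 * centers[mode_idx] - up_c[1:][::-1], up_c])
    sym_n = np.concatenate([up_n[1:][::-1], up_n])
    total = sym_n.sum()
    mean = float((sym_c * sym_n).sum() / total)
    sd = float(np.sqrt((sym_n * (sym_c - mean) ** 2).sum() / total))

    hist = TrimmedHistogram(
        bin_centers=centers,
        counts=counts,
        mode_hu=float(centers[mode_idx]),
        mode_count=float(counts[mode_idx]),
        trim_bounds=(float(centers[0]), float(centers[-1])),
        sym_mean=mean,
        sym_sd=sd,
    )
    t_at = mean + cfg.t_at_sd_factor * sd
    return float(t_at), hist
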