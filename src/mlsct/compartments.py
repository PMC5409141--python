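"""Partition of the analysis slab into calibrated tissue compartments.

Within the slab, the fascia splits subcutaneous fat (SAT) from the
intrafascial volume; inside the fascia the method distinguishes perimuscular
adipose tissue (PAT, fascia-connected fat below the adipose threshold T_AT),
anatomical muscle M (intrafascia minus PAT minus bone, i.e. muscle tissue plus
embedded lipids), GMM-defined muscle tissue MT, and the six muscle
concentration bins spanning T_AT (0%) to T_HDM (100%), with high-density
muscle HDM at >= 100% and intermuscular fat IMAT at < 0%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from ._morphology import STRUCT26, label26, largest_components
from .calibration import CalibrationContext, TrimmedHistogram
from .config import AnalysisConfig
from .volume import CTVolume, VoxelMask

__all__ = [
    "GMMFit",
    "ConcentrationMap",
    "segment_sat",
    "segment_pat_and_m",
    "fit_gmm",
    "gaussian_intersection",
    "segment_mt",
    "concentration_bins",
    "BIN_CODES",
]

#: concentration-bin label codes (0 = outside the binned domain)
BIN_CODES = {"IMAT": 1, "B2": 2, "B3": 3, "B4": 4, "B5": 5, "B6": 6}


def segment_sat(
    voi_us: VoxelMask, voi_if: VoxelMask, dermis_mask: np.ndarray
) -> VoxelMask:
    """SAT = analysis slab minus intrafascia minus the dermis-connected set.

    The largest remaining component per leg (at most two) is kept, discarding
    stray debris such as table or air pockets.
    """
    raw = voi_us.data & ~voi_if.data & ~dermis_mask
    comps = largest_components(raw, 2)
    if not comps:
        raise ValueError("SAT segmentation came up empty")
    sat = np.zeros_like(raw)
    for c in comps:
        sat |= c
    return VoxelMask(sat, "VOI_SAT", voi_us.spacing)


def segment_pat_and_m(
    vol: CTVolume,
    voi_if: VoxelMask,
    fascia_surface: np.ndarray,
    t_at: float,
    femur_mask: VoxelMask,
    femur_dilation: int = 1,
) -> tuple[VoxelMask, VoxelMask]:
    """Split the intrafascial volume into PAT and anatomical muscle.

    PAT is grown (26-connected) from fascia-adjacent interior voxels whose HU
    is strictly below T_AT; isolated lipid islands (EML) stay inside M by
    construction.  M = VOI_IF minus PAT minus the dilated femur, so the three
    pieces tile VOI_IF exactly.
    """
    fem = femur_mask.data
    if femur_dilation > 0:
        fem = ndimage.binary_dilation(fem, STRUCT26, iterations=femur_dilation)
    # the surface layer of VOI_IF *is* the fascia; PAT grows strictly inside it
    low = (vol.data < t_at) & voi_if.data & ~fem & ~fascia_surface
    labels, _ = label26(low)
    adj = ndimage.binary_dilation(fascia_surface, STRUCT26) & low
    touching = np.unique(labels[adj])
    touching = touching[touching > 0]
    pat = np.isin(labels, touching)
    m = voi_if.data & ~pat & ~fem
    return (
        VoxelMask(pat, "VOI_PAT", voi_if.spacing),
        VoxelMask(m, "VOI_M", voi_if.spacing),
    )


# ---------------------------------------------------------------------------
# Two-Gaussian decomposition of the MLS spectrum
# ---------------------------------------------------------------------------


@dataclass
class GMMFit:
    """Two-Gaussian fit of the MLS HU spectrum (adipose + muscle tissue)."""

    at_height: float
    at_mean: float
    at_sd: float
    mt_height: float
    mt_mean: float
    mt_sd: float
    intersection_a: float
    residual_norm: float
    converged: bool

    @property
    def peak_b(self) -> float:
        """Peak of the muscle-tissue curve (its mean)."""
        return self.mt_mean

    def at_curve(self, x: np.ndarray) -> np.ndarray:
        return self.at_height * np.exp(-((x - self.at_mean) ** 2) / (2 * self.at_sd**2))

    def mt_curve(self, x: np.ndarray) -> np.ndarray:
        return self.mt_height * np.exp(-((x - self.mt_mean) ** 2) / (2 * self.mt_sd**2))

    def validate(self) -> "GMMFit":
        if self.at_sd <= 0 or self.mt_sd <= 0:
            raise ValueError("fitted SDs must be positive")
        if not (self.at_mean < self.intersection_a < self.mt_mean):
            raise ValueError(
                f"intersection a={self.intersection_a:.1f} must lie between the "
                f"component means ({self.at_mean:.1f}, {self.mt_mean:.1f})"
            )
        return self

    def to_json(self, hu_range: tuple[float, float] = (-200.0, 200.0)) -> str:
        x = np.arange(hu_range[0], hu_range[1] + 1.0)
        return json.dumps(
            {
                "at": {"height": self.at_height, "mean": self.at_mean, "sd": self.at_sd},
                "mt": {"height": self.mt_height, "mean": self.mt_mean, "sd": self.mt_sd},
                "intersection_a": self.intersection_a,
                "peak_b": self.peak_b,
                "residual_norm": self.residual_norm,
                "converged": self.converged,
                "curves": {
                    "hu": x.tolist(),
                    "at": self.at_curve(x).tolist(),
                    "mt": self.mt_curve(x).tolist(),
                },
            }
        )


def gaussian_intersection(h1, m1, s1, h2, m2, s2) -> float:
    """The equal-density HU between two Gaussian curves, within (m1, m2).

    Solving h1*exp(-(x-m1)^2/2s1^2) = h2*exp(-(x-m2)^2/2s2^2) is a quadratic
    in x; the root between the means is returned (for equal SDs the equation
    is linear).
    """
    if m1 > m2:
        h1, m1, s1, h2, m2, s2 = h2, m2, s2, h1, m1, s1
    A = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    B = m1 / (s1**2) - m2 / (s2**2)
    C = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + np.log(h1 / h2)
    if abs(A) < 1e-12:
        if abs(B) < 1e-12:
            return 0.5 * (m1 + m2)
        roots = np.array([-C / B])
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            return 0.5 * (m1 + m2)
        sq = np.sqrt(disc)
        roots = np.array([(-B - sq) / (2 * A), (-B + sq) / (2 * A)])
    inside = roots[(roots > m1) & (roots < m2)]
    if len(inside):
        return float(inside[0])
    # fall back to the root nearest the inter-mean interval
    mid = 0.5 * (m1 + m2)
    return float(roots[np.argmin(np.abs(roots - mid))])


def fit_gmm(
    vol: CTVolume,
    voi_mls: VoxelMask,
    sat_star: TrimmedHistogram,
    ctx: CalibrationContext,
    cfg: AnalysisConfig | None = None,
) -> GMMFit:
    """Least-squares two-Gaussian decomposition of the MLS spectrum.

    The 1-HU-bin count histogram of VOI_MLS (= VOI_SAT u VOI_IF) inside the
    configured HU window is fit with the sum of an adipose and a muscle
    Gaussian by Levenberg-Marquardt.  Initialization: the adipose component
    takes the height, peak and width of SAT*; the muscle component height is
    the VOI_AT / VOI_MLS voxel ratio times the modal count, its peak starts
    at the phantom-anchored T_HDM.
    """
    cfg = cfg or AnalysisConfig()
    if not voi_mls.data.any():
        raise ValueError("VOI_MLS is empty")
    lo, hi = cfg.gmm_hu_window
    vals = vol.data[voi_mls.data]
    vals = vals[(vals >= lo) & (vals <= hi)]
    v = np.rint(vals).astype(np.int64)
    centers = np.arange(v.min(), v.max() + 1, dtype=np.float64)
    counts = np.bincount(v - v.min()).astype(np.float64)

    modal = counts.max()
    at_h0 = max(sat_star.mode_count, 1.0)
    at_m0 = sat_star.mode_hu
    at_s0 = max(sat_star.sym_sd, 1.0)
    ratio = ctx.n_voi_at / max(voi_mls.count(), 1)
    mt_h0 = max(ratio * modal, 1.0)
    mt_m0 = ctx.t_hdm
    mt_s0 = at_s0

    def model(p, x):
        h1, m1, s1, h2, m2, s2 = p
        return h1 * np.exp(-((x - m1) ** 2) / (2 * s1**2)) + h2 * np.exp(
            -((x - m2) ** 2) / (2 * s2**2)
        )

    def resid(p):
        q = p.copy()
        q[2] = abs(q[2]) + 1e-6
        q[5] = abs(q[5]) + 1e-6
        return model(q, centers) - counts

    x0 = np.array([at_h0, at_m0, at_s0, mt_h0, mt_m0, mt_s0], dtype=float)
    res = least_squares(resid, x0, method="lm", max_nfev=cfg.gmm_max_iter)
    h1, m1, s1, h2, m2, s2 = res.x
    s1, s2 = abs(s1) + 1e-6, abs(s2) + 1e-6
    if m1 > m2:  # keep the adipose component on the left
        h1, m1, s1, h2, m2, s2 = h2, m2, s2, h1, m1, s1
    converged = bool(res.success and h1 > 0 and h2 > 0 and (m2 - m1) > 1.0)
    a = gaussian_intersection(h1, m1, s1, h2, m2, s2)
    fit = GMMFit(
        at_height=float(h1),
        at_mean=float(m1),
        at_sd=float(s1),
        mt_height=float(h2),
        mt_mean=float(m2),
        mt_sd=float(s2),
        intersection_a=float(a),
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=converged,
    )
    return fit


def segment_mt(
    vol: CTVolume,
    voi_if: VoxelMask,
    fit: GMMFit,
    femur_mask: VoxelMask,
    femur_dilation: int = 1,
) -> VoxelMask:
    """Muscle tissue: growing from supra-peak seeds, accepting supra-a voxels.

    26-connected volume growing inside VOI_IF (dilated femur excluded) starts
    from voxels with HU strictly above the muscle-tissue peak b and accepts
    voxels with HU strictly above the adipose/muscle intersection a.
    """
    if not fit.converged:
        raise ValueError("refusing to segment MT from a non-convergent GMM fit")
    fit.validate()
    fem = femur_mask.data
    if femur_dilation > 0:
        fem = ndimage.binary_dilation(fem, STRUCT26, iterations=femur_dilation)
    domain = voi_if.data & ~fem
    accept = (vol.data > fit.intersection_a) & domain
    seeds = (vol.data > fit.peak_b) & domain
    if not seeds.any():
        warnings.warn("no voxels above the muscle-tissue peak; VOI_MT is empty", stacklevel=2)
        return VoxelMask(np.zeros_like(domain), "VOI_MT", voi_if.spacing)
    labels, _ = label26(accept)
    keep = np.unique(labels[seeds])
    keep = keep[keep > 0]
    mt = np.isin(labels, keep)
    return VoxelMask(mt, "VOI_MT", voi_if.spacing)


@dataclass
class ConcentrationMap:
    """Per-voxel muscle concentration (%) and its bin label over VOI_IF."""

    concentration: np.ndarray   # float32, % (valid on the domain)
    bin_labels: np.ndarray      # uint8 per BIN_CODES, 0 outside the domain
    domain: np.ndarray          # VOI_IF minus the dilated femur

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.bin_labels == code).sum()) for name, code in BIN_CODES.items()
        }

    def mask(self, name: str, spacing) -> VoxelMask:
        return VoxelMask(self.bin_labels == BIN_CODES[name], f"VOI_{name}", spacing)


def concentration_bins(
    vol: CTVolume,
    voi_if: VoxelMask,
    ctx: CalibrationContext,
    femur_mask: VoxelMask,
    femur_dilation: int = 1,
) -> ConcentrationMap:
    """Linear muscle-concentration rescaling and the six printed bins.

    concentration = 100 * (HU - T_AT) / (T_HDM - T_AT), floored to integer
    percent so the printed ranges partition the domain: IMAT < 0%, B2 0-24%,
    B3 25-49%, B4 50-74%, B5 75-99%, B6 (= HDM) >= 100%.
    """
    if ctx.t_at is None or not (ctx.t_at < ctx.t_hdm):
        raise ValueError("concentration bins require T_AT < T_HDM")
    fem = femur_mask.data
    if femur_dilation > 0:
        fem = ndimage.binary_dilation(fem, STRUCT26, iterations=femur_dilation)
    domain = voi_if.data & ~fem
    conc = 100.0 * (vol.data.astype(np.float64) - ctx.t_at) / (ctx.t_hdm - ctx.t_at)
    pct = np.floor(conc).astype(np.int64)
    bins = np.zeros(vol.shape, dtype=np.uint8)
    bins[domain & (pct < 0)] = BIN_CODES["IMAT"]
    bins[domain & (pct >= 0) & (pct <= 24)] = BIN_CODES["B2"]
    bins[domain & (pct >= 25) & (pct <= 49)] = BIN_CODES["B3"]
    bins[domain & (pct >= 50) & (pct <= 74)] = BIN_CODES["B4"]
    bins[domain & (pct >= 75) & (pct <= 99)] = BIN_CODES["B5"]
    bins[domain & (pct >= 100)] = BIN_CODES["B6"]
    return ConcentrationMap(
        concentration=conc.astype(np.float32), bin_labels=bins, domain=domain
    )
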