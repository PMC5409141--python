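"""Synthetic CT thigh phantoms with full ground truth.

The phantom emulates, per axial slice, the concentric tissue model of the
mid-thigh: an air background, two legs built from nested elliptic cylinders
(dermis shell, subcutaneous adipose tissue, a thin deep fascia, perimuscular
adipose pockets on the inner fascia side, anatomical muscle, femoral bone),
optional extramyocellular lipid speckles inside the muscle, optional
edema/vessel blobs in the SAT, and a small water-insert cylinder below the
legs standing in for the in-scan calibration phantom.  Legs get a small,
smooth per-slice center jitter so no stage can rely on perfect cylinders.

Muscle appearance dials
-----------------------
``lipid_infiltration`` lowers the mean muscle HU toward adipose values
("washed-out" appearance); ``eml_speckle_density`` adds adipose-valued grains
("moth-eaten" appearance).  A smooth low-frequency HU texture of amplitude
``muscle_texture_amp`` emulates intramyocellular-lipid heterogeneity of real
muscle; it keeps noiseless histograms from degenerating into delta spikes.

Everything is deterministic for a fixed ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import CTVolume, VoxelMask

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "LABELS",
    "generate_thigh_phantom",
    "add_gaussian_noise",
    "noise_sd_for_exposure_change",
    "analytic_sat_volume_mm3",
]

#: label codes of the ground-truth map
LABELS = {
    "air": 0,
    "dermis": 1,
    "SAT": 2,
    "fascia": 3,
    "PAT": 4,
    "EML": 5,
    "muscle": 6,
    "femur": 7,
    "water": 8,
    "edema": 9,
}
_NAMES = {v: k for k, v in LABELS.items()}


class PhantomGeometryError(ValueError):
    """The requested radii/thicknesses violate tissue containment."""


@dataclass
class PhantomSpec:
    """Geometry, tissue HU means and degradation dials of a thigh phantom.

    Defaults produce a 256 x 256 x 60 grid at 1 mm isotropic spacing with two
    legs (dermis outer semi-axes 52 x 50 mm), SAT at -100 HU, muscle at 40 HU
    and 10 HU Gaussian noise.
    """

    grid_shape: tuple[int, int, int] = (256, 256, 60)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    leg_radii_mm: tuple[float, float] = (52.0, 50.0)   # dermis outer semi-axes
    dermis_thickness_vox: int = 2
    sat_thickness_mm: float = 9.0
    fascia_thickness_vox: int = 2
    pat_rind_thickness_vox: int = 5
    pat_coverage: float = 0.5          # fraction of circumference with PAT pockets
    pat_pocket_count: int = 4
    femur_radius_mm: float = 9.0
    water_insert_radius_mm: float = 8.0

    hu: dict = field(
        default_factory=lambda: {
            "air": -1000.0,
            "dermis": 100.0,
            "SAT": -100.0,
            "fascia": -40.0,
            "internal_at": -110.0,     # PAT and EML: slightly leaner than SAT
            "muscle": 40.0,
            "bone": 700.0,
            "water": 0.0,
            "edema": 20.0,
        }
    )

    lipid_infiltration: float = 0.0    # 0..1, shifts muscle HU toward adipose
    eml_speckle_density: float = 0.03  # volume fraction of muscle occupied by EML
    eml_grain_diameter_mm: float = 3.0
    edema_blob_count: int = 2
    edema_blob_radius_mm: float = 4.0
    muscle_texture_amp: float = 2.0    # SD (HU) of smooth intramuscular texture
    sat_texture_amp: float = 3.5       # SD (HU) of smooth subcutaneous-fat texture
    jitter_vox: float = 0.5            # per-slice leg-center wobble amplitude
    bridge_halfheight_vox: int = 4     # soft-tissue bridge joining the legs

    noise_sd: float = 10.0             # additive Gaussian noise SD (HU)
    acetabulum_end_slice: int = 2
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> "PhantomSpec":
        if any(n < 8 for n in self.grid_shape):
            raise PhantomGeometryError(f"grid too small: {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomGeometryError(f"spacing must be positive: {self.spacing}")
        for nm in ("dermis_thickness_vox", "fascia_thickness_vox", "pat_rind_thickness_vox"):
            if getattr(self, nm) < 0:
                raise PhantomGeometryError(f"{nm} must be >= 0")
        if self.sat_thickness_mm <= 0 or self.femur_radius_mm <= 0:
            raise PhantomGeometryError("sat_thickness_mm and femur_radius_mm must be > 0")
        if not (0.0 <= self.lipid_infiltration <= 1.0):
            raise PhantomGeometryError("lipid_infiltration must lie in [0, 1]")
        if self.noise_sd < 0:
            raise PhantomGeometryError("noise_sd must be >= 0")
        # containment chain femur < fascia inner < fascia outer < SAT outer < dermis outer
        r = self._ring_semiaxes()
        inner = min(r["fascia_inner"])
        if inner <= self.femur_radius_mm + 2.0:
            raise PhantomGeometryError(
                "containment violated: femur must fit inside the fascia "
                f"(fascia inner semi-axis {inner:.1f} mm vs femur {self.femur_radius_mm:.1f} mm)"
            )
        for outer_k, inner_k in [
            ("dermis_outer", "sat_outer"),
            ("sat_outer", "fascia_outer"),
            ("fascia_outer", "fascia_inner"),
        ]:
            if min(np.subtract(r[outer_k], r[inner_k])) < 0:
                raise PhantomGeometryError(
                    f"containment violated: {inner_k} exceeds {outer_k}"
                )
        # both legs plus the insert must fit on the grid
        nx, ny = self.grid_shape[0], self.grid_shape[1]
        ax, ay = r["dermis_outer"]
        cxs = self._leg_centers_mm()
        for cx, cy in cxs:
            if cx - ax < 1 or cx + ax > nx * self.spacing[0] - 1:
                raise PhantomGeometryError("containment violated: leg exceeds grid in x")
            if cy - ay < 1 or cy + ay + 2 * self.water_insert_radius_mm > ny * self.spacing[1]:
                raise PhantomGeometryError(
                    "containment violated: leg plus water insert exceeds grid in y"
                )
        hu = self.hu
        if not (hu["air"] < hu["SAT"] < hu["water"] < hu["muscle"] < hu["bone"]):
            raise PhantomGeometryError(
                "tissue HU ordering air < SAT < water < muscle < bone violated"
            )
        if not (hu["SAT"] < hu["fascia"] < hu["muscle"]):
            raise PhantomGeometryError("fascia HU must lie between SAT and muscle")
        return self

    # -- derived geometry -----------------------------------------------
    def _ring_semiaxes(self) -> dict:
        sp = min(self.spacing[0], self.spacing[1])
        ax, ay = self.leg_radii_mm
        derm = self.dermis_thickness_vox * sp
        fasc = self.fascia_thickness_vox * sp
        return {
            "dermis_outer": (ax, ay),
            "sat_outer": (ax - derm, ay - derm),
            "fascia_outer": (ax - derm - self.sat_thickness_mm, ay - derm - self.sat_thickness_mm),
            "fascia_inner": (
                ax - derm - self.sat_thickness_mm - fasc,
                ay - derm - self.sat_thickness_mm - fasc,
            ),
        }

    def _leg_centers_mm(self) -> list[tuple[float, float]]:
        nx, ny = self.grid_shape[0], self.grid_shape[1]
        ax, ay = self.leg_radii_mm
        gap = 0.5 * (nx * self.spacing[0] - 4 * ax) / 3.0
        cy = ay + 2.0
        return [
            (2 * gap + ax, cy),
            (nx * self.spacing[0] - 2 * gap - ax, cy),
        ]

    def to_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        return json.dumps(d, sort_keys=True, indent=1)


@dataclass
class GroundTruth:
    """Exhaustive, mutually exclusive label map plus the operator inputs."""

    labels: np.ndarray                 # uint8, same grid as the volume
    spacing: tuple[float, float, float]
    acetabulum_end_slice: int
    noise_sd: float
    gap_seeds: list[tuple[int, int, int]]   # suggested seeds inside PAT pockets
    spec: PhantomSpec

    def mask(self, *names: str, name: str | None = None) -> VoxelMask:
        sel = np.isin(self.labels, [LABELS[n] for n in names])
        return VoxelMask(sel, name or "+".join(names), self.spacing)

    def true_volumes_mm3(self) -> dict:
        vv = float(np.prod(self.spacing))
        counts = np.bincount(self.labels.ravel(), minlength=len(LABELS))
        return {_NAMES[i]: float(c * vv) for i, c in enumerate(counts) if i in _NAMES}

    # -- compartment truths by the method's own definitions --------------
    def intrafascia(self) -> VoxelMask:
        """Fascia sheet plus everything it encloses."""
        return self.mask("fascia", "PAT", "EML", "muscle", "femur", name="IF_truth")

    def sat_region(self) -> VoxelMask:
        """Subcutaneous compartment: SAT plus any blobs embedded in it."""
        return self.mask("SAT", "edema", name="SAT_truth")

    def anatomical_muscle(self, femur_dilation_vox: int = 1) -> VoxelMask:
        """Intrafascia minus PAT minus the dilated femur (fascia sheet stays in)."""
        fem = self.mask("femur").data
        if femur_dilation_vox > 0:
            fem = ndimage.binary_dilation(
                fem, np.ones((3, 3, 3), bool), iterations=femur_dilation_vox
            )
        m = self.intrafascia().data & ~self.mask("PAT").data & ~fem
        return VoxelMask(m, "M_truth", self.spacing)

    def write_summary(self, path: str) -> None:
        payload = {
            "true_volumes_mm3": self.true_volumes_mm3(),
            "acetabulum_end_slice": self.acetabulum_end_slice,
            "noise_sd": self.noise_sd,
            "gap_seeds": [list(s) for s in self.gap_seeds],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------


def analytic_sat_volume_mm3(spec: PhantomSpec) -> float:
    """Closed-form volume of the SAT annuli (both legs, full z extent)."""
    r = spec._ring_semiaxes()
    area = np.pi * (
        r["sat_outer"][0] * r["sat_outer"][1] - r["fascia_outer"][0] * r["fascia_outer"][1]
    )
    return float(2.0 * area * spec.grid_shape[2] * spec.spacing[2])


def _stamp_spheres(
    target: np.ndarray, eligible: np.ndarray, count: int, radius_vox: float, rng
) -> np.ndarray:
    """Place ``count`` digital spheres with centers drawn from ``eligible``."""
    out = np.zeros_like(target, dtype=bool)
    idx = np.argwhere(eligible)
    if len(idx) == 0 or count <= 0:
        return out
    centers = idx[rng.choice(len(idx), size=min(count, len(idx)), replace=False)]
    r = int(np.ceil(radius_vox))
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    ball = (xx**2 + yy**2 + zz**2) <= radius_vox**2
    shp = target.shape
    for c in centers:
        sl_t, sl_b = [], []
        ok = True
        for ax in range(3):
            lo, hi = c[ax] - r, c[ax] + r + 1
            blo = max(0, -lo)
            bhi = ball.shape[ax] - max(0, hi - shp[ax])
            lo, hi = max(lo, 0), min(hi, shp[ax])
            if hi <= lo:
                ok = False
                break
            sl_t.append(slice(lo, hi))
            sl_b.append(slice(blo, bhi))
        if ok:
            out[tuple(sl_t)] |= ball[tuple(sl_b)]
    return out


def generate_thigh_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Render a thigh phantom and its ground truth.

    Deterministic for a fixed ``spec.seed``: the same spec yields bit-identical
    volumes.  Voxel HU = tissue mean (+ muscle texture) + N(0, noise_sd).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    X = x[:, None]
    Y = y[None, :]

    rings = spec._ring_semiaxes()
    centers = spec._leg_centers_mm()
    # smooth per-slice wobble of each leg center
    ph = rng.uniform(0, 2 * np.pi, size=(2, 2))
    zfrac = np.arange(nz) / max(nz, 1)
    jit = spec.jitter_vox * min(sx, sy)

    pocket_w = (
        2 * np.pi * spec.pat_coverage / spec.pat_pocket_count
        if spec.pat_pocket_count
        else 0.0
    )
    pocket_starts = [
        2 * np.pi * p / spec.pat_pocket_count for p in range(spec.pat_pocket_count)
    ]
    gap_seeds: list[tuple[int, int, int]] = []

    for leg, (cx0, cy0) in enumerate(centers):
        for k in range(nz):
            cx = cx0 + jit * np.sin(2 * np.pi * zfrac[k] + ph[leg, 0])
            cy = cy0 + jit * np.sin(4 * np.pi * zfrac[k] + ph[leg, 1])
            dx = X - cx
            dy = Y - cy

            def inside(semi):
                return (dx / semi[0]) ** 2 + (dy / semi[1]) ** 2 <= 1.0

            derm = inside(rings["dermis_outer"])
            sat_o = inside(rings["sat_outer"])
            fas_o = inside(rings["fascia_outer"])
            fas_i = inside(rings["fascia_inner"])
            sl = labels[:, :, k]
            sl[derm & ~sat_o] = LABELS["dermis"]
            sl[sat_o & ~fas_o] = LABELS["SAT"]
            sl[fas_o & ~fas_i] = LABELS["fascia"]
            sl[fas_i] = LABELS["muscle"]
            # PAT pockets: angular sectors of a rind just inside the fascia
            if spec.pat_rind_thickness_vox > 0 and pocket_w > 0:
                rind_semi = (
                    rings["fascia_inner"][0] - spec.pat_rind_thickness_vox * sx,
                    rings["fascia_inner"][1] - spec.pat_rind_thickness_vox * sy,
                )
                rind = fas_i & ~inside(rind_semi)
                theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
                in_pocket = np.zeros_like(rind)
                for t0 in pocket_starts:
                    span = np.mod(theta - t0, 2 * np.pi) < pocket_w
                    in_pocket |= span
                sl[rind & in_pocket] = LABELS["PAT"]
            fem = (dx**2 + dy**2) <= spec.femur_radius_mm**2
            sl[fem] = LABELS["femur"]

        # seed suggestions: pocket sector centers at a few slice positions
        for t0 in pocket_starts:
            tmid = t0 + pocket_w / 2.0
            rmid = 0.5 * (
                rings["fascia_inner"][0]
                + rings["fascia_inner"][0]
                - spec.pat_rind_thickness_vox * sx
            )
            for k in (nz // 4, nz // 2, 3 * nz // 4):
                cx = cx0 + jit * np.sin(2 * np.pi * zfrac[k] + ph[leg, 0])
                cy = cy0 + jit * np.sin(4 * np.pi * zfrac[k] + ph[leg, 1])
                i = int((cx + rmid * np.cos(tmid)) / sx)
                j = int((cy + rmid * np.sin(tmid)) / sy)
                if 0 <= i < nx and 0 <= j < ny and labels[i, j, k] == LABELS["PAT"]:
                    gap_seeds.append((i, j, k))

    # soft-tissue bridge joining the legs (perineal tissue of a hip scan):
    # keeps the body one connected component, classified with the dermis
    if spec.bridge_halfheight_vox > 0:
        h = spec.bridge_halfheight_vox
        cy_idx = int(centers[0][1] / sy)
        x_lo = int(centers[0][0] / sx)
        x_hi = int(centers[1][0] / sx)
        band = np.zeros(spec.grid_shape, dtype=bool)
        band[x_lo:x_hi, max(cy_idx - h, 0) : cy_idx + h + 1, :] = True
        labels[band & (labels == LABELS["air"])] = LABELS["dermis"]

    # EML speckles: adipose grains inside the muscle, away from its border
    if spec.eml_speckle_density > 0:
        grain_r = 0.5 * spec.eml_grain_diameter_mm / min(sx, sy, sz)
        muscle = labels == LABELS["muscle"]
        deep = ndimage.distance_transform_edt(muscle) > grain_r + 1.5
        grain_vox = max(1.0, 4.0 / 3.0 * np.pi * grain_r**3)
        n_grain = int(spec.eml_speckle_density * muscle.sum() / grain_vox)
        eml = _stamp_spheres(labels, deep, n_grain, grain_r, rng) & muscle
        labels[eml] = LABELS["EML"]

    # edema / vessel blobs embedded in the SAT
    if spec.edema_blob_count > 0:
        blob_r = spec.edema_blob_radius_mm / min(sx, sy, sz)
        sat = labels == LABELS["SAT"]
        deep = ndimage.distance_transform_edt(sat) > blob_r + 1.5
        blobs = _stamp_spheres(labels, deep, spec.edema_blob_count, blob_r, rng) & sat
        labels[blobs] = LABELS["edema"]

    # water insert cylinder below the legs
    cyi = ny * sy - spec.water_insert_radius_mm - 1.0
    cxi = 0.5 * nx * sx
    ins = ((X - cxi) ** 2 + (Y - cyi) ** 2) <= spec.water_insert_radius_mm**2
    labels[np.broadcast_to(ins[:, :, None], labels.shape) & (labels == 0)] = LABELS["water"]

    # -- HU rendering ---------------------------------------------------
    hu = spec.hu
    muscle_mean = (
        hu["muscle"] * (1.0 - spec.lipid_infiltration)
        + hu["internal_at"] * spec.lipid_infiltration
    )
    lut = np.zeros(len(LABELS), dtype=np.float64)
    lut[LABELS["air"]] = hu["air"]
    lut[LABELS["dermis"]] = hu["dermis"]
    lut[LABELS["SAT"]] = hu["SAT"]
    lut[LABELS["fascia"]] = hu["fascia"]
    lut[LABELS["PAT"]] = hu["internal_at"]
    lut[LABELS["EML"]] = hu["internal_at"]
    lut[LABELS["muscle"]] = muscle_mean
    lut[LABELS["femur"]] = hu["bone"]
    lut[LABELS["water"]] = hu["water"]
    lut[LABELS["edema"]] = hu["edema"]
    data = lut[labels]

    if spec.muscle_texture_amp > 0 or spec.sat_texture_amp > 0:
        tex = rng.standard_normal(size=spec.grid_shape)
        tex = ndimage.gaussian_filter(tex, sigma=4.0)
        sd = tex.std()
        if sd > 0:
            tex /= sd
        data = np.where(
            labels == LABELS["muscle"], data + spec.muscle_texture_amp * tex, data
        )
        data = np.where(labels == LABELS["SAT"], data + spec.sat_texture_amp * tex, data)

    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    vol = CTVolume(data=data.astype(np.float32), spacing=spec.spacing)
    gt = GroundTruth(
        labels=labels,
        spacing=spec.spacing,
        acetabulum_end_slice=spec.acetabulum_end_slice,
        noise_sd=spec.noise_sd,
        gap_seeds=gap_seeds,
        spec=spec,
    )
    return vol, gt


def add_gaussian_noise(vol: CTVolume, sd_add: float, seed: int) -> CTVolume:
    """Add independent zero-mean Gaussian noise of SD ``sd_add`` (HU)."""
    if sd_add < 0:
        raise ValueError(f"sd_add must be >= 0, got {sd_add}")
    if sd_add == 0:
        return vol.with_data(vol.data.copy())
    rng = np.random.default_rng(seed)
    return vol.with_data(vol.data + rng.normal(0.0, sd_add, size=vol.shape))


def noise_sd_for_exposure_change(sd_current: float, mode: str, param: float) -> float:
    """SD of the noise to *add* so the total noise matches a lower exposure.

    ``multiplier`` mode: target total SD = ``param`` x current, so
    sd_add = sd_current * sqrt(param**2 - 1) (independent variances add).
    ``mAs`` mode: quantum-noise model SD proportional to 1/sqrt(mAs);
    ``param`` = (mAs_old, mAs_new), sd_add = sd_current * sqrt(old/new - 1).
    """
    if sd_current < 0:
        raise ValueError("sd_current must be >= 0")
    if mode == "multiplier":
        k = float(param)
        if k < 1:
            raise ValueError(f"cannot remove noise: multiplier {k} < 1")
        return sd_current * float(np.sqrt(k * k - 1.0))
    if mode == "mAs":
        old, new = (float(p) for p in param)
        if new > old:
            raise ValueError(f"cannot remove noise: mAs {new} > {old}")
        if new <= 0:
            raise ValueError("mAs_new must be > 0")
        return sd_current * float(np.sqrt(old / new - 1.0))
    raise ValueError(f"mode must be 'multiplier' or 'mAs', got {mode!r}")
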