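"""Pipeline configuration: every empirical constant, overridable and validated.

Defaults are the operating point of the method: 70% surface threshold, the
[-190, -30] HU adipose growing range, 10-voxel muscle depth, the 15-voxel
candidate band around the fascia approximation, 65% ray-shielding quorum, 30%
histogram trim, the 35 HU high-density-muscle constant and the +/-2 SD factors.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import yaml

log = logging.getLogger("mlsct")

__all__ = ["AnalysisConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration value is outside its permissible range."""


def _rng(name, value, lo, hi):
    if not (lo <= value <= hi):
        raise ConfigError(f"{name}={value!r} outside permissible range [{lo}, {hi}]")


@dataclass
class AnalysisConfig:
    # --- surface / analysis VOI ---
    surface_threshold_fraction: float = 0.70   # T_surf = min + frac*(max-min)
    surface_sphere_radius_vox: int = 10

    # --- adipose reference growing ---
    at_growing_range_hu: tuple[float, float] = (-190.0, -30.0)
    at_min_region_voxels: int = 500

    # --- fascia segmentation ---
    muscle_min_depth_vox: float = 10.0         # condition 1: depth from surface
    candidate_band_vox: float = 15.0           # max Euclidean distance from FA
    shielding_fraction: float = 0.65           # quorum of 26 rays
    local_sd_factor: float = 2.0               # g: HU >= mean26 - factor*SD26
    closing_semiaxes_vox: tuple[float, float, float] = (5.0, 5.0, 10.0)
    smoothing_radius_vox: float = 2.0          # opening+closing ball
    femur_dilation_vox: int = 1

    # --- calibration ---
    histogram_trim_fraction: float = 0.30      # cut bins < 30% of modal count
    t_at_sd_factor: float = 2.0                # T_AT = mean + 2 SD of SAT*
    hdm_constant_hu: float = 35.0              # T_HDM = const + CT_H2O
    ct_h2o: float | None = None                # explicit override; else insert ROI

    # --- GMM / muscle tissue ---
    gmm_hu_window: tuple[float, float] = (-200.0, 200.0)
    gmm_max_iter: int = 2000

    # --- features ---
    granulometry_step_mm: float = 1.0
    fd_on_boundary: bool = True

    # free-form extras are rejected: catching typos beats silently ignoring them

    def validate(self) -> "AnalysisConfig":
        _rng("surface_threshold_fraction", self.surface_threshold_fraction, 0.0, 1.0)
        _rng("surface_sphere_radius_vox", self.surface_sphere_radius_vox, 1, 100)
        lo, hi = self.at_growing_range_hu
        if lo >= hi:
            raise ConfigError(f"at_growing_range_hu must be increasing, got {(lo, hi)}")
        _rng("muscle_min_depth_vox", self.muscle_min_depth_vox, 0.0, 100.0)
        _rng("candidate_band_vox", self.candidate_band_vox, 1.0, 100.0)
        _rng("shielding_fraction", self.shielding_fraction, 0.0, 1.0)
        _rng("local_sd_factor", self.local_sd_factor, 0.0, 10.0)
        _rng("smoothing_radius_vox", self.smoothing_radius_vox, 0.0, 20.0)
        _rng("femur_dilation_vox", self.femur_dilation_vox, 0, 10)
        _rng("histogram_trim_fraction", self.histogram_trim_fraction, 0.0, 1.0)
        _rng("t_at_sd_factor", self.t_at_sd_factor, 0.0, 10.0)
        _rng("hdm_constant_hu", self.hdm_constant_hu, -500.0, 500.0)
        _rng("granulometry_step_mm", self.granulometry_step_mm, 0.01, 50.0)
        if any(s <= 0 for s in self.closing_semiaxes_vox):
            raise ConfigError("closing_semiaxes_vox must be positive")
        wlo, whi = self.gmm_hu_window
        if wlo >= whi:
            raise ConfigError(f"gmm_hu_window must be increasing, got {(wlo, whi)}")
        return self

    @property
    def shielding_quorum(self) -> int:
        """Minimum reflected rays out of 26 (ceil of the quorum fraction)."""
        import math
        return math.ceil(self.shielding_fraction * 26)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(getattr(cls(), f.name), tuple):
                kwargs[f.name] = tuple(kwargs[f.name])
        return cls(**kwargs).validate()


def grade_in_range(G: int) -> int:
    """Validate the operator muscle-appearance grade G in {1, 2, 3}."""
    G = int(G)
    if G not in (1, 2, 3):
        raise ConfigError(f"grade G={G} outside permissible range [1, 3]")
    return G


def load_config(path: str | None) -> AnalysisConfig:
    """Load a YAML/JSON config; missing keys take defaults, extras are errors.

    The effective configuration is logged so every run records the constants
    it actually used.
    """
    if path is None:
        cfg = AnalysisConfig().validate()
    else:
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text) if text.strip() else {}
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
        cfg = AnalysisConfig.from_dict(data)
    log.info("effective config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg
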