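"""Measurement models: map model states to observables and assign variances.

Three observables are supported:

* flow-cytometry fluorescence (A.U.): linear in mature reporter concentration
  with an autofluorescence background.  The error model is heteroscedastic:
  the standard deviation grows linearly with the mean signal above an
  estimated lower detection limit of 2037 A.U.; every point below the limit
  is assigned a fixed variance of 2344 (A.U. scale).  The default slope is
  calibrated for continuity at the limit, (slope * 2037)^2 = 2344.
* relative reporter mRNA (vs the ACT1 reference, absorbed into one scaling
  factor).
* specific growth rate (1/min) with a 10% relative measurement error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "MeasurementConfig",
    "fluorescence_readout",
    "flow_variance",
    "mrna_relative",
    "growth_sd",
]

DETECTION_LIMIT_AU = 2037.0
FLOOR_VARIANCE_AU = 2344.0


@dataclass(frozen=True)
class MeasurementConfig:
    s_f: float = 100.0  # fluorescence scale, A.U. per nM mature reporter
    bg_f: float = 400.0  # autofluorescence background, A.U.
    detection_limit: float = DETECTION_LIMIT_AU
    floor_variance: float = FLOOR_VARIANCE_AU
    sd_slope: float = math.sqrt(FLOOR_VARIANCE_AU) / DETECTION_LIMIT_AU
    s_m: float = 2.0  # mRNA scale, relative units per nM
    mrna_rel_error: float = 0.15  # synthetic-data relative s.d. for mRNA
    mrna_sd_floor: float = 0.02  # relative units
    growth_rel_error: float = 0.10

    def __post_init__(self):
        for name in ("s_f", "bg_f", "detection_limit", "floor_variance",
                     "sd_slope", "s_m", "growth_rel_error"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # variance must be continuous or increasing at the detection limit
        if (self.sd_slope * self.detection_limit) ** 2 < self.floor_variance * (1 - 1e-9):
            raise ValueError("variance would drop when crossing the detection limit")

    @classmethod
    def from_params(cls, params: ParameterSet) -> "MeasurementConfig":
        """Couple the two estimated scaling factors to a parameter set."""
        return cls(s_f=params["s_f"], s_m=params["s_m"])


def fluorescence_readout(rep_mat_nm, cfg: MeasurementConfig):
    """Mean fluorescence (A.U.) for a mature-reporter concentration (nM)."""
    rep = np.asarray(rep_mat_nm, dtype=float)
    if np.any(rep < 0):
        raise ValueError("reporter concentration must be >= 0")
    out = cfg.s_f * rep + cfg.bg_f
    return float(out) if np.ndim(rep_mat_nm) == 0 else out


def flow_variance(mean_au, cfg: MeasurementConfig):
    """Measurement variance (A.U. scale) for a mean fluorescence signal."""
    mean = np.asarray(mean_au, dtype=float)
    if np.any(mean < 0):
        raise ValueError("mean fluorescence must be >= 0")
    var = np.where(
        mean < cfg.detection_limit, cfg.floor_variance, (cfg.sd_slope * mean) ** 2
    )
    return float(var) if np.ndim(mean_au) == 0 else var


def mrna_relative(mrna_rep_nm, cfg: MeasurementConfig):
    """Reporter mRNA relative to the constitutive reference transcript."""
    m = np.asarray(mrna_rep_nm, dtype=float)
    if np.any(m < 0):
        raise ValueError("mRNA concentration must be >= 0")
    out = cfg.s_m * m
    return float(out) if np.ndim(mrna_rep_nm) == 0 else out


def growth_sd(mu_obs, cfg: MeasurementConfig):
    """Standard deviation of a specific growth-rate measurement."""
    mu = np.asarray(mu_obs, dtype=float)
    if np.any(mu < 0):
        raise ValueError("growth rate must be >= 0")
    out = cfg.growth_rel_error * mu
    return float(out) if np.ndim(mu_obs) == 0 else out
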