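"""Named model parameters, bounds, and the shipped default set.

All concentrations are in nM and all times in minutes.  Bimolecular rate
constants therefore carry 1/(nM min), unimolecular ones 1/min.  Each
parameter is marked free (subject to estimation) or fixed; the default
configuration marks exactly 45 parameters free: 43 kinetic constants plus the
two measurement scaling factors (fluorescence and mRNA), mirroring the size
of the estimation problem the model was built for.  Bounds are expressed in
log10 space, by default +/- 3 decades around the default value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Tuple

__all__ = ["Parameter", "ParameterSet", "default_parameters", "AFFINITY_IDS"]

UNITS = ("per_min", "per_nM_per_min", "nM", "dimensionless")

#: ids of the four AD-polymerase dissociation constants (nM)
AFFINITY_IDS = ("kd_ad_b42", "kd_ad_b112", "kd_ad_gal4ad", "kd_ad_vp16")


@dataclass(frozen=True)
class Parameter:
    value: float
    unit: str
    free: bool = True
    bounds: Tuple[float, float] | None = None  # (low, high) in log10

    def __post_init__(self):
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.value <= 0:
            raise ValueError("parameter values must be positive")
        lo, hi = self.log_bounds
        if not (lo <= math.log10(self.value) <= hi):
            raise ValueError("value outside bounds")

    @property
    def log_bounds(self) -> Tuple[float, float]:
        if self.bounds is not None:
            return self.bounds
        lv = math.log10(self.value)
        return (lv - 3.0, lv + 3.0)


class ParameterSet:
    """Mapping of parameter id -> :class:`Parameter` with convenience access."""

    def __init__(self, entries: Dict[str, Parameter]):
        self.entries = dict(entries)

    def __getitem__(self, name: str) -> float:
        return self.entries[name].value

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def free_ids(self) -> Tuple[str, ...]:
        return tuple(n for n, p in self.entries.items() if p.free)

    def values_tuple(self) -> Tuple[float, ...]:
        """Hashable snapshot of all values (stable order)."""
        return tuple(self.entries[n].value for n in sorted(self.entries))

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.entries)

    def with_values(self, updates: Dict[str, float]) -> "ParameterSet":
        """New set with some values replaced (bounds are widened if needed)."""
        entries = dict(self.entries)
        for name, value in updates.items():
            p = entries[name]
            lo, hi = p.log_bounds
            lv = math.log10(value)
            bounds = (min(lo, lv), max(hi, lv))
            entries[name] = replace(p, value=float(value), bounds=bounds)
        return ParameterSet(entries)

    def log_bounds(self, ids: Iterable[str]) -> Dict[str, Tuple[float, float]]:
        return {n: self.entries[n].log_bounds for n in ids}


def default_parameters() -> ParameterSet:
    """The shipped default parameter set.

    The four AD-polymerase dissociation constants are the published point
    estimates (0.8 mM, 4 uM, 200 nM, 27 nM for B42, B112, Gal4AD, VP16).  The
    remaining constants are calibration values chosen so that the canonical
    simulations reproduce the system's documented behaviours (box-number
    scaling, induction fold, toxicity onset, mRNA rise time); see
    docs/methods.md for the calibration rationale.
    """
    P = Parameter
    per_min = "per_min"
    bi = "per_nM_per_min"
    nM = "nM"
    e = {
        # hormone exchange (medium <-> cytoplasm <-> nucleus)
        "k_h_in": P(0.2, per_min),
        "k_h_out": P(0.2, per_min, free=False),
        "k_h_nc": P(0.2, per_min),
        "k_h_cn": P(0.2, per_min, free=False),
        # inhibitor retention of the hormone-free factor
        "k_ti_on": P(1e-3, bi),
        "k_ti_off": P(0.1, per_min),
        # hormone binding (Kd ~ 100 nM in both compartments)
        "k_th_on": P(1e-3, bi),
        "k_th_off": P(0.1, per_min),
        "k_th_on_n": P(1e-3, bi),
        "k_th_off_n": P(0.1, per_min),
        # nucleocytoplasmic transport
        "k_tfh_in": P(0.1, per_min),
        "k_tfh_out": P(0.01, per_min),
        "k_tf_out": P(0.05, per_min, free=False),
        "k_tf_in": P(0.005, per_min, free=False),
        "k_pol_in": P(0.1, per_min),
        # squelching on-rate; dissociation = k_sq_on * Kd(AD)
        "k_sq_on": P(1e-3, bi),
        # AD-polymerase dissociation constants (published estimates)
        "kd_ad_b42": P(8.0e5, nM),
        "kd_ad_b112": P(4.0e3, nM),
        "kd_ad_gal4ad": P(200.0, nM),
        "kd_ad_vp16": P(27.0, nM),
        # constitutive genes: Pol binding / unbinding / transcription
        "k_gb_tf": P(2e-3, bi),
        "k_gu_tf": P(1.0, per_min),
        "k_tx_tf": P(1.0, per_min),
        "k_gb_i": P(2e-3, bi),
        "k_gu_i": P(1.0, per_min),
        "k_tx_i": P(1.0, per_min),
        "k_gb_pol": P(8e-3, bi),
        "k_gu_pol": P(0.3, per_min),
        "k_tx_pol": P(1.0, per_min),
        # operator binding by the activated factor
        "k_op_on": P(4.755e-5, bi),
        "k_op_off": P(0.073, per_min),
        # activated and basal recruitment, target transcription
        "k_act": P(2622.0, per_min),
        "k_basal": P(1.403e-6, bi),
        "k_tx_rep": P(1.0, per_min),
        # translation (scaled by the growth-dependent factor)
        "k_tl_tf": P(5.503, per_min),
        "k_tl_i": P(2.0, per_min),
        "k_tl_pol": P(0.12, per_min),
        "k_tl_rep": P(1.0, per_min),
        # reporter maturation and constitutive red-reporter synthesis
        "k_mat": P(0.033, per_min, free=False),
        "k_red": P(0.05, per_min, free=False),
        # mRNA turnover
        "k_deg_mtf": P(0.05, per_min),
        "k_deg_mi": P(0.05, per_min),
        "k_deg_mpol": P(0.05, per_min),
        "k_deg_mrep": P(0.05, per_min),
        # protein turnover per moiety class
        "k_deg_tf": P(0.05, per_min),
        "k_deg_i": P(0.01, per_min),
        "k_deg_pol": P(0.004, per_min),
        "k_deg_rep": P(0.008, per_min),
        "k_deg_red": P(0.001, per_min),
        # measurement scaling factors (estimated alongside the kinetics)
        "s_f": P(100.0, "dimensionless"),
        "s_m": P(2.0, "dimensionless"),
    }
    return ParameterSet(e)
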