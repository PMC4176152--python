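"""Run configuration: a single human-readable YAML file, schema-checked.

The default configuration ships with the package and carries the anchored
measurement-model constants; user files override any subset of keys.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Optional

import yaml

from .dynamics import GrowthConfig, MEDIA
from .measurement import MeasurementConfig
from .network import VARIANTS
from .params import ParameterSet, default_parameters

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


_SECTIONS = {"network", "measurement", "growth", "estimation", "design", "paths"}


@dataclass
class RunConfig:
    variant: str
    n_boxes: int
    nop_n_factor: bool
    pol_total_mode: str
    measurement: MeasurementConfig
    growth: Dict[str, GrowthConfig]
    seed: int
    budget: int
    design_seed: int
    design_noise: bool
    out_dir: Path
    params: ParameterSet
    raw: dict

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def growth_for(self, medium: str) -> GrowthConfig:
        try:
            return self.growth[medium]
        except KeyError:
            raise ConfigError(f"no growth configuration for medium {medium!r}")


def _deep_update(base: dict, overrides: dict) -> dict:
    out = dict(base)
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: Optional[str] = None) -> RunConfig:
    """Load the packaged defaults, optionally overlaid with a user file."""
    with resources.files("tfdyn.data").joinpath("default.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - _SECTIONS
        if unknown:
            raise ConfigError(f"unknown config sections {sorted(unknown)}")
        raw = _deep_update(raw, user)

    net = raw["network"]
    if net["variant"] not in VARIANTS:
        raise ConfigError(f"unknown variant {net['variant']!r}")
    if not 1 <= int(net["n_boxes"]) <= 8:
        raise ConfigError("n_boxes must be in 1..8")
    if net["pol_total_mode"] not in ("moiety", "free_nuclear"):
        raise ConfigError("pol_total_mode must be 'moiety' or 'free_nuclear'")

    m = raw["measurement"]
    mcfg = MeasurementConfig(
        s_f=float(m["s_f"]),
        bg_f=float(m["bg_f"]),
        detection_limit=float(m["detection_limit"]),
        floor_variance=float(m["floor_variance"]),
        s_m=float(m["s_m"]),
        growth_rel_error=float(m["growth_rel_error"]),
    )

    g = raw["growth"]
    growth = {
        medium: GrowthConfig(
            mu_max=float(g[medium]), k_mmu=float(g["k_mmu"]), n_hmu=float(g["n_hmu"])
        )
        for medium in MEDIA
    }

    est = raw["estimation"]
    seed, budget = int(est["seed"]), int(est["budget"])
    if budget < 1:
        raise ConfigError("estimation budget must be positive")

    params = default_parameters().with_values({"s_f": mcfg.s_f, "s_m": mcfg.s_m})

    return RunConfig(
        variant=net["variant"],
        n_boxes=int(net["n_boxes"]),
        nop_n_factor=bool(net["nop_n_factor"]),
        pol_total_mode=net["pol_total_mode"],
        measurement=mcfg,
        growth=growth,
        seed=seed,
        budget=budget,
        design_seed=int(raw["design"]["seed"]),
        design_noise=bool(raw["design"]["noise"]),
        out_dir=Path(raw["paths"]["out_dir"]),
        params=params,
        raw=raw,
    )
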