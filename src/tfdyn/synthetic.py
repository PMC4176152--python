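"""Synthetic datasets emulating the experimental design under which the
LexA-ER-AD system was characterised.

No public raw datasets exist for the system (its published characterisation
reports figures only), so the pipeline is exercised on synthetic data
generated from the model itself: four activation-domain variants, a two-fold beta-estradiol dose
ladder from 0 to 2500 nM, fluorescence time courses to 28 h, reporter-mRNA
time courses to 2 h, exponential-phase specific growth rates 5 h after
induction, promoters with 1-8 lexA boxes, and three media (SDC glucose,
SGlyC glycerol, SDP proline-nitrogen).

The default design partitions exactly like the original calibration: the
training subset (4 boxes, SDC) holds 446 points, matching 401 degrees of
freedom plus 45 estimated parameters, and the validation subset (all other
conditions) holds 1014 points.

Noise follows the measurement models: Gaussian with the flow-cytometry
variance model for fluorescence, 15% relative (floored) for mRNA, 10%
relative for growth rates; draws are truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .dynamics import Condition, simulate
from .estimation import DATASET_COLUMNS, DataError, TimecourseDataset
from .measurement import (
    MeasurementConfig,
    fluorescence_readout,
    flow_variance,
    growth_sd,
    mrna_relative,
)
from .params import ParameterSet, default_parameters

__all__ = [
    "DesignSpec",
    "default_design",
    "generate",
    "write_dataset",
    "read_dataset",
    "GROWTH_READ_TIME_MIN",
]

#: growth rates are read 5 h after induction (exponential phase)
GROWTH_READ_TIME_MIN = 300.0

DOSES_NM = (0.0, 3.9, 7.8, 15.0, 31.0, 62.0, 125.0, 250.0, 500.0, 1000.0, 2000.0, 2500.0)
GROWTH_DOSES_NM = DOSES_NM + (312.0,)
FLUOR_TIMES_MIN = (60.0, 120.0, 180.0, 300.0, 600.0, 1200.0, 1440.0, 1680.0)
MRNA_TIMES_MIN = (0.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 75.0, 90.0, 120.0)


@dataclass(frozen=True)
class DesignSpec:
    """Full factorial-ish design plus the generating truth.

    ``extra_conditions`` lists (variant, n_boxes, medium, dose, observable,
    times) tuples appended verbatim (used for the high-dose VP16 time course).
    """

    variants: Tuple[str, ...]
    box_counts: Tuple[int, ...]
    media: Tuple[str, ...]
    doses_nM: Tuple[float, ...]
    growth_doses_nM: Tuple[float, ...]
    fluor_times_min: Tuple[float, ...]
    mrna_times_min: Tuple[float, ...]
    seed: int = 1
    noise: bool = True
    mrna_variants: Tuple[str, ...] = ("B42",)
    mrna_dose_nM: float = 2000.0
    extra_conditions: Tuple = ()

    def __post_init__(self):
        for grid in (self.doses_nM, self.fluor_times_min, self.mrna_times_min):
            arr = np.asarray(grid, float)
            if len(arr) == 0 or np.any(np.diff(arr) <= 0):
                raise DataError("design grids must be non-empty and increasing")


def default_design(seed: int = 1, noise: bool = True) -> DesignSpec:
    """The canonical design emulating the published characterisation.

    Dose ladder 0-2500 nM through the reported doses (15, 125, 312,
    2000, 2500 nM); fluorescence readings at 1-28 h; reporter-mRNA readings
    within the first 2 h (including the 15 min first-signal and 45 min
    half-induction anchors); growth rates at 5 h.  Training subset (4 boxes,
    SDC): 4 variants x 12 doses x 8 fluorescence times (384) + one 10-point
    mRNA series (B42, 2000 nM) + 4 variants x 13 growth doses (52) = 446.
    """
    return DesignSpec(
        variants=("B42", "B112", "Gal4AD", "VP16"),
        box_counts=(1, 2, 3, 4, 8),
        media=("SDC", "SGlyC", "SDP"),
        doses_nM=DOSES_NM,
        growth_doses_nM=tuple(sorted(GROWTH_DOSES_NM)),
        fluor_times_min=FLUOR_TIMES_MIN,
        mrna_times_min=MRNA_TIMES_MIN,
        seed=seed,
        noise=noise,
        extra_conditions=(
            # high-dose VP16 toxicity time course outside the training medium
            ("VP16", 4, "SGlyC", 2500.0, "fluorescence", FLUOR_TIMES_MIN),
        ),
    )


def _design_rows(design: DesignSpec) -> List[Dict]:
    """Enumerate the design as noise-free placeholder rows."""
    rows: List[Dict] = []

    def add(variant, n_boxes, medium, dose, observable, times):
        eid = f"{observable[:5]}_{variant}_{n_boxes}box_{medium}_{dose:g}nM"
        for t in times:
            rows.append(
                dict(
                    experiment_id=eid,
                    variant=variant,
                    n_boxes=int(n_boxes),
                    medium=medium,
                    dose_nM=float(dose),
                    time_min=float(t),
                    observable=observable,
                )
            )

    # training block: all variants, 4 boxes, SDC
    for v in design.variants:
        for d in design.doses_nM:
            add(v, 4, "SDC", d, "fluorescence", design.fluor_times_min)
    for v in design.mrna_variants:
        add(v, 4, "SDC", design.mrna_dose_nM, "mrna_rel", design.mrna_times_min)
    for v in design.variants:
        # one growth-rate dose-response experiment per variant
        eid = f"growth_{v}_4box_SDC"
        for d in design.growth_doses_nM:
            rows.append(
                dict(
                    experiment_id=eid,
                    variant=v,
                    n_boxes=4,
                    medium="SDC",
                    dose_nM=float(d),
                    time_min=GROWTH_READ_TIME_MIN,
                    observable="growth_rate",
                )
            )
    # validation: box-count series for B42 and B112 in SDC
    for v in ("B42", "B112"):
        if v not in design.variants:
            continue
        for nb in design.box_counts:
            if nb == 4:
                continue
            for d in design.doses_nM:
                add(v, nb, "SDC", d, "fluorescence", design.fluor_times_min)
    # validation: alternative media for B42, 4 boxes
    for medium in design.media:
        if medium == "SDC":
            continue
        for d in design.doses_nM:
            add("B42", 4, medium, d, "fluorescence", design.fluor_times_min)
        add("B42", 4, medium, design.mrna_dose_nM, "mrna_rel", design.mrna_times_min)
        eid = f"growth_B42_4box_{medium}"
        for d in design.growth_doses_nM:
            rows.append(
                dict(
                    experiment_id=eid,
                    variant="B42",
                    n_boxes=4,
                    medium=medium,
                    dose_nM=float(d),
                    time_min=GROWTH_READ_TIME_MIN,
                    observable="growth_rate",
                )
            )
    for variant, nb, medium, dose, observable, times in design.extra_conditions:
        add(variant, nb, medium, dose, observable, times)
    return rows


def generate(
    design: DesignSpec,
    params: Optional[ParameterSet] = None,
    measurement: Optional[MeasurementConfig] = None,
    **opts,
) -> TimecourseDataset:
    """Simulate the design and apply the measurement-noise models.

    Reproducible given ``design.seed``; with ``design.noise`` off the values
    equal the model readouts exactly (the recorded standard deviations are
    the same either way, so a noise-free dataset evaluates to chi2 = 0 at the
    generating parameters).
    """
    params = params or default_parameters()
    cfg = measurement or MeasurementConfig.from_params(params)
    frame = pd.DataFrame(_design_rows(design))
    rng = np.random.default_rng(design.seed)

    # one simulation per condition over the union of requested times
    values = np.empty(len(frame))
    sds = np.empty(len(frame))
    for key, block in frame.groupby(["variant", "n_boxes", "medium", "dose_nM"], sort=True):
        variant, n_boxes, medium, dose = key
        times = np.unique(np.concatenate([[0.0], block["time_min"].to_numpy(float)]))
        cond = Condition(variant, int(n_boxes), medium, float(dose))
        try:
            traj = simulate(cond, params, times, **opts)
        except Exception as err:
            raise RuntimeError(f"simulation failed for condition {cond}") from err
        tindex = {t: i for i, t in enumerate(traj.time)}
        for ridx, row in block.iterrows():
            i = tindex[float(row["time_min"])]
            obs = row["observable"]
            if obs == "fluorescence":
                mean = fluorescence_readout(max(traj.series("Rep_mat")[i], 0.0), cfg)
                sd = float(np.sqrt(flow_variance(mean, cfg)))
            elif obs == "mrna_rel":
                mean = mrna_relative(max(traj.series("mRNA_rep")[i], 0.0), cfg)
                sd = max(cfg.mrna_rel_error * mean, cfg.mrna_sd_floor)
            else:
                mean = float(traj.mu[i])
                sd = max(growth_sd(mean, cfg), 1e-6)
            values[ridx] = mean
            sds[ridx] = sd

    if design.noise:
        values = np.maximum(values + rng.standard_normal(len(frame)) * sds, 0.0)
    frame["value"] = values
    frame["sd"] = sds
    frame["role"] = np.where(
        (frame["n_boxes"] == 4) & (frame["medium"] == "SDC"), "training", "validation"
    )
    return TimecourseDataset(frame[DATASET_COLUMNS])


def write_dataset(dataset: TimecourseDataset, path) -> None:
    """Write as CSV (header, UTF-8, '.' decimal); lossless round-trip."""
    dataset.frame.to_csv(path, index=False, encoding="utf-8")


def read_dataset(path) -> TimecourseDataset:
    """Read a dataset CSV; malformed rows raise with the offending line."""
    frame = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    for col in ("dose_nM", "time_min", "value", "sd"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad) > 0:
            # +2: header line plus 1-based indexing
            raise DataError(f"{path}: non-numeric {col!r} on line {bad[0] + 2}")
        if coerced.isna().any():
            raise DataError(f"{path}: missing {col!r} on line {coerced.index[coerced.isna()][0] + 2}")
        frame[col] = coerced
    frame["n_boxes"] = frame["n_boxes"].astype(int)
    return TimecourseDataset(frame[DATASET_COLUMNS])
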