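"""Chi-squared objective, evolutionary-strategy fitting, and model testing.

The objective is the per-experiment 1/n_i-weighted sum of squared
standardised residuals,

    chi2(theta) = sum_i (1/n_i) sum_j ((c_ij^obs - c_ij^model) / sd_ij)^2,

over experiments i with n_i points each.  Parameters are searched in log10
space inside box bounds by a CMA-type evolutionary strategy; simulation
failures at a candidate point are penalised rather than raised so the search
survives stiff corners of parameter space.  Model adequacy is judged by the
left tail of the chi-squared distribution at the appropriate degrees of
freedom (data points minus estimated parameters).

For speed the dataset is compiled once into flat arrays (condition index,
time index, observable code per point); each objective evaluation then runs
one simulation per unique condition and gathers readouts without touching
pandas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import Condition, IntegrationError, simulate
from .es import cma_es_minimize
from .measurement import MeasurementConfig
from .params import ParameterSet

__all__ = [
    "DATASET_COLUMNS",
    "OBSERVABLES",
    "TimecourseDataset",
    "FitResult",
    "chi_squared",
    "evolutionary_fit",
    "goodness_of_fit",
    "split_train_validation",
    "predict_validation",
    "SIM_FAILURE_PENALTY",
    "DataError",
]

DATASET_COLUMNS = [
    "experiment_id",
    "variant",
    "n_boxes",
    "medium",
    "dose_nM",
    "time_min",
    "observable",
    "value",
    "sd",
    "role",
]

OBSERVABLES = ("fluorescence", "mrna_rel", "growth_rate")
_OBS_CODE = {name: i for i, name in enumerate(OBSERVABLES)}

SIM_FAILURE_PENALTY = 1e9


class DataError(ValueError):
    pass


@dataclass
class TimecourseDataset:
    """Observed (or simulated) points with per-point standard deviations.

    Thin wrapper around a tidy DataFrame with the canonical columns; one
    experiment (one ``experiment_id``) is a time or dose series of a single
    observable under one construct/medium context.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in DATASET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataError(f"dataset is missing columns {missing}")
        if len(self.frame) == 0:
            raise DataError("dataset is empty")
        if (self.frame["sd"] <= 0).any():
            raise DataError("all standard deviations must be positive")
        bad = set(self.frame["observable"]) - set(OBSERVABLES)
        if bad:
            raise DataError(f"unknown observables {sorted(bad)}")
        self._compiled: Optional[_CompiledData] = None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_points(self) -> int:
        return len(self.frame)

    def experiments(self) -> Iterable[Tuple[str, pd.DataFrame]]:
        return self.frame.groupby("experiment_id", sort=True)

    def subset(self, mask) -> "TimecourseDataset":
        return TimecourseDataset(self.frame[mask].reset_index(drop=True))

    @property
    def roles(self) -> set:
        return set(self.frame["role"])

    def compiled(self) -> "_CompiledData":
        if self._compiled is None:
            self._compiled = _CompiledData.from_frame(self.frame)
        return self._compiled


@dataclass
class _CompiledData:
    """Flat-array view of a dataset for fast repeated objective evaluation."""

    conditions: List[Condition]
    tgrids: List[np.ndarray]
    row_cond: np.ndarray  # (n,) condition index
    row_tidx: np.ndarray  # (n,) index into the condition's time grid
    row_obs: np.ndarray  # (n,) observable code
    values: np.ndarray
    sds: np.ndarray
    row_weight: np.ndarray  # (n,) 1/n_i of the row's experiment
    exp_index: np.ndarray  # (n,) experiment ordinal
    exp_ids: List[str]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "_CompiledData":
        cond_keys: Dict[Tuple, int] = {}
        cond_times: List[set] = []
        keys = list(
            zip(frame["variant"], frame["n_boxes"].astype(int),
                frame["medium"], frame["dose_nM"].astype(float))
        )
        times = frame["time_min"].to_numpy(float)
        for key, t in zip(keys, times):
            idx = cond_keys.setdefault(key, len(cond_keys))
            if idx == len(cond_times):
                cond_times.append(set())
            cond_times[idx].add(float(t))
        conditions = [Condition(*key) for key in cond_keys]
        tgrids = [
            np.unique(np.concatenate([[0.0], sorted(ts)])) for ts in cond_times
        ]
        tindex = [{t: i for i, t in enumerate(tg)} for tg in tgrids]
        n = len(frame)
        row_cond = np.fromiter((cond_keys[k] for k in keys), dtype=np.int64, count=n)
        row_tidx = np.fromiter(
            (tindex[ci][float(t)] for ci, t in zip(row_cond, times)),
            dtype=np.int64, count=n,
        )
        row_obs = frame["observable"].map(_OBS_CODE).to_numpy(np.int64)
        exp_codes, exp_ids = pd.factorize(frame["experiment_id"], sort=True)
        n_i = np.bincount(exp_codes).astype(float)
        return cls(
            conditions=conditions,
            tgrids=tgrids,
            row_cond=row_cond,
            row_tidx=row_tidx,
            row_obs=row_obs,
            values=frame["value"].to_numpy(float),
            sds=frame["sd"].to_numpy(float),
            row_weight=1.0 / n_i[exp_codes],
            exp_index=exp_codes,
            exp_ids=list(exp_ids),
        )

    def predict(self, params: ParameterSet, cfg: MeasurementConfig, **opts) -> np.ndarray:
        """Model readout for every data row (may raise IntegrationError)."""
        pred = np.empty(len(self.values))
        for ci, (cond, tg) in enumerate(zip(self.conditions, self.tgrids)):
            mask = self.row_cond == ci
            if not mask.any():
                continue
            traj = simulate(cond, params, tg, **opts)
            tidx = self.row_tidx[mask]
            obs = self.row_obs[mask]
            out = np.empty(mask.sum())
            rep = np.maximum(traj.series("Rep_mat")[tidx], 0.0)
            mrna = np.maximum(traj.series("mRNA_rep")[tidx], 0.0)
            out = np.where(
                obs == 0,
                cfg.s_f * rep + cfg.bg_f,
                np.where(obs == 1, cfg.s_m * mrna, traj.mu[tidx]),
            )
            pred[mask] = out
        return pred


@dataclass
class FitResult:
    theta: ParameterSet
    chi2: float
    n_points: int
    n_free: int
    seed: int
    evaluations: int
    converged: bool = True
    message: str = ""

    @property
    def dof(self) -> int:
        return self.n_points - self.n_free

    @property
    def p_left(self) -> float:
        return goodness_of_fit(self.chi2, self.n_points, self.n_free)[1]

    def to_json(self, free_ids: Optional[Sequence[str]] = None) -> str:
        ids = list(free_ids) if free_ids is not None else list(self.theta.free_ids)
        return json.dumps(
            {
                "theta_hat": {n: self.theta[n] for n in ids},
                "chi2": self.chi2,
                "n_points": self.n_points,
                "n_free": self.n_free,
                "dof": self.dof,
                "p_left": self.p_left,
                "seed": self.seed,
                "evaluations": self.evaluations,
                "converged": self.converged,
                "message": self.message,
            },
            indent=2,
        )


def chi_squared(
    params: ParameterSet,
    dataset: TimecourseDataset,
    measurement: Optional[MeasurementConfig] = None,
    penalty: float = SIM_FAILURE_PENALTY,
    **opts,
) -> float:
    """1/n_i-weighted chi-squared of the model against a dataset.

    A simulation failure at the supplied parameter point returns ``penalty``
    instead of raising, so optimisers can treat it as a very bad candidate.
    """
    cfg = measurement or MeasurementConfig.from_params(params)
    data = dataset.compiled()
    try:
        pred = data.predict(params, cfg, **opts)
    except (IntegrationError, FloatingPointError, ValueError, RuntimeError):
        return float(penalty)
    if not np.all(np.isfinite(pred)):
        return float(penalty)
    resid = (data.values - pred) / data.sds
    return float(np.sum(resid * resid * data.row_weight))


def goodness_of_fit(chi2: float, n_points: int, n_free: int) -> Tuple[int, float]:
    """Degrees of freedom and the left-tail chi-squared probability.

    ``p_left`` is P(X <= chi2) for X ~ chi2(dof); small values mean the fit
    agrees with the data to better than measurement noise would allow, values
    near 1 mean significant misfit.
    """
    dof = int(n_points) - int(n_free)
    if dof <= 0:
        raise DataError("degrees of freedom must be positive")
    return dof, float(stats.chi2.cdf(chi2, dof))


def evolutionary_fit(
    dataset: TimecourseDataset,
    free_ids: Sequence[str],
    params: ParameterSet,
    seed: int,
    budget: int,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    measurement: Optional[MeasurementConfig] = None,
    popsize: Optional[int] = None,
    strategy: Callable = cma_es_minimize,
    **opts,
) -> FitResult:
    """Fit ``free_ids`` to the dataset with an evolutionary strategy.

    The search runs in log10-parameter space within box bounds (default: each
    parameter's own bounds, i.e. +/-3 decades around its current value).
    Deterministic given ``seed``; ``budget`` caps objective evaluations.
    """
    free_ids = list(free_ids)
    if not free_ids:
        raise DataError("at least one free parameter is required")
    all_bounds = params.log_bounds(free_ids)
    if bounds:
        all_bounds.update(bounds)
    box = [all_bounds[n] for n in free_ids]

    def objective(x: np.ndarray) -> float:
        trial = params.with_values({n: 10.0 ** xv for n, xv in zip(free_ids, x)})
        cfg = measurement
        if cfg is None:
            cfg = MeasurementConfig.from_params(trial)
        return chi_squared(trial, dataset, measurement=cfg, **opts)

    res = strategy(objective, box, seed=seed, budget=budget, popsize=popsize)
    theta = params.with_values({n: 10.0 ** xv for n, xv in zip(free_ids, res.x_best)})
    return FitResult(
        theta=theta,
        chi2=float(res.f_best),
        n_points=dataset.n_points,
        n_free=len(free_ids),
        seed=seed,
        evaluations=res.evaluations,
        converged=res.converged,
        message=res.message,
    )


def split_train_validation(dataset: TimecourseDataset) -> TimecourseDataset:
    """Label rows: training = {4 lexA boxes, SDC medium}, validation = rest."""
    frame = dataset.frame.copy()
    train = (frame["n_boxes"] == 4) & (frame["medium"] == "SDC")
    frame["role"] = np.where(train, "training", "validation")
    if not train.any():
        raise DataError("training partition (4 boxes, SDC) is empty")
    return TimecourseDataset(frame)


def predict_validation(
    theta: ParameterSet,
    dataset: TimecourseDataset,
    measurement: Optional[MeasurementConfig] = None,
    **opts,
) -> Dict:
    """Simulate the validation partition at the fitted parameters.

    Only condition-specific quantities (the medium's maximal growth rate and
    translation-capacity scaling) change between conditions; no model
    parameter is re-estimated, so the pooled degrees of freedom equal the
    validation point count.
    """
    val = dataset.subset(dataset.frame["role"] == "validation")
    cfg = measurement or MeasurementConfig.from_params(theta)
    data = val.compiled()
    pred = data.predict(theta, cfg, **opts)
    resid2 = ((data.values - pred) / data.sds) ** 2
    per_exp = np.bincount(data.exp_index, weights=resid2 * data.row_weight)
    n_per_exp = np.bincount(data.exp_index)
    total = float(per_exp.sum())
    dof, p_left = goodness_of_fit(total, val.n_points, 0)
    return {
        "chi2": total,
        "n_points": val.n_points,
        "dof": dof,
        "p_left": p_left,
        "predictions": pred,
        "per_experiment": pd.DataFrame(
            {
                "experiment_id": data.exp_ids,
                "n_points": n_per_exp,
                "chi2_weighted": per_exp,
            }
        ),
    }
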