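"""Covariance-matrix-adapting evolutionary strategy (CMA-ES).

A compact, deterministic (seeded) implementation of the standard (mu/mu_w,
lambda) CMA-ES with cumulative step-size adaptation and rank-1 plus rank-mu
covariance updates, for box-constrained minimisation in a continuous search
space (here: log10 parameter space).  Box constraints are handled by
projecting sampled candidates onto the box before evaluation and penalising
the squared projection distance, which keeps the strategy's internal state
consistent while never evaluating the objective outside the bounds.

The interface is a single function so that a different strategy (e.g. a plain
(mu, lambda)-ES) can be swapped in by the estimation layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = ["ESResult", "cma_es_minimize"]


@dataclass
class ESResult:
    x_best: np.ndarray
    f_best: float
    evaluations: int
    generations: int
    converged: bool
    message: str


def cma_es_minimize(
    fun: Callable[[np.ndarray], float],
    bounds: Sequence[Tuple[float, float]],
    seed: int,
    budget: int,
    x0: Optional[np.ndarray] = None,
    sigma0: Optional[float] = None,
    popsize: Optional[int] = None,
    tol_fun: float = 1e-6,
    tol_x: float = 1e-9,
    penalty: float = 1e4,
) -> ESResult:
    """Minimise ``fun`` over the box ``bounds`` with at most ``budget`` evaluations.

    Deterministic given ``seed``.  ``x0`` defaults to the box centre and
    ``sigma0`` to a quarter of the smallest box width.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("bounds must satisfy low < high")
    d = len(bounds)
    lam = popsize if popsize is not None else 4 + int(3 * math.log(d))
    if budget < lam:
        raise ValueError("budget must be at least the population size")
    mean = np.clip(np.asarray(x0, float) if x0 is not None else (lo + hi) / 2, lo, hi)
    sigma = float(sigma0) if sigma0 is not None else float(np.min(hi - lo)) / 4.0

    # standard CMA-ES strategy constants
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)
    cc = (4 + mu_eff / d) / (d + 4 + 2 * mu_eff / d)
    cs = (mu_eff + 2) / (d + mu_eff + 5)
    c1 = 2 / ((d + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((d + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, math.sqrt((mu_eff - 1) / (d + 1)) - 1) + cs
    chi_d = math.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d * d))

    rng = np.random.default_rng(seed)
    pc = np.zeros(d)
    ps = np.zeros(d)
    C = np.eye(d)
    B = np.eye(d)
    D = np.ones(d)
    invsqrtC = np.eye(d)
    eigen_stale = 0

    x_best = mean.copy()
    f_best = math.inf
    evals = 0
    gen = 0
    history: list[float] = []
    converged = False
    message = "budget exhausted"

    while evals + lam <= budget:
        gen += 1
        z = rng.standard_normal((lam, d))
        y = z @ (B * D).T  # y ~ N(0, C)
        xs = mean + sigma * y
        xs_feas = np.clip(xs, lo, hi)
        fs = np.empty(lam)
        for i in range(lam):
            f = float(fun(xs_feas[i]))
            if not math.isfinite(f):
                f = penalty * 1e3
            # quadratic penalty keeps selection pressure toward the box
            f += penalty * float(np.sum((xs[i] - xs_feas[i]) ** 2))
            fs[i] = f
        evals += lam
        order = np.argsort(fs, kind="stable")
        if fs[order[0]] < f_best:
            f_best = float(fs[order[0]])
            x_best = xs_feas[order[0]].copy()
        sel = y[order[:mu]]
        y_w = w @ sel
        mean = np.clip(mean + sigma * y_w, lo, hi)

        ps = (1 - cs) * ps + math.sqrt(cs * (2 - cs) * mu_eff) * (invsqrtC @ y_w)
        hsig = (
            np.linalg.norm(ps) / math.sqrt(1 - (1 - cs) ** (2 * gen)) / chi_d
            < 1.4 + 2 / (d + 1)
        )
        pc = (1 - cc) * pc + (1.0 if hsig else 0.0) * math.sqrt(
            cc * (2 - cc) * mu_eff
        ) * y_w
        rank_mu = (sel * w[:, None]).T @ sel
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (0.0 if hsig else 1.0) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        sigma *= math.exp((cs / damps) * (np.linalg.norm(ps) / chi_d - 1))

        eigen_stale += 1
        if eigen_stale > max(1, int(1 / (10 * d * (c1 + cmu)))):
            eigen_stale = 0
            C = (C + C.T) / 2
            eigvals, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(eigvals, 1e-30))
            invsqrtC = B @ np.diag(1.0 / D) @ B.T

        history.append(float(fs[order[0]]))
        span = 10 + int(30 * d / lam)
        if len(history) > span:
            recent = history[-span:]
            if max(recent) - min(recent) < tol_fun * max(1.0, abs(f_best)):
                converged = True
                message = "objective stagnated (tol_fun)"
                break
        if sigma * float(np.max(D)) < tol_x:
            converged = True
            message = "search distribution collapsed (tol_x)"
            break

    return ESResult(
        x_best=x_best,
        f_best=f_best,
        evaluations=evals,
        generations=gen,
        converged=converged,
        message=message,
    )
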