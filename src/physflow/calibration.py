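"""Parameter fitting against historical field totals.

Two routes are provided: an exhaustive 0.01-step grid over
``(p_enter, p_GP)`` for the 2-field model, and a projected
numeric-gradient descent with seeded random restarts for an arbitrary
number of fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import InflowSeries
from .eurostat_io import CountryConfig
from .supply_model import ModelParams, ModelRun, gamma_array, initialize, run


@dataclass
class FitResult:
    """Outcome of a calibration: best parameters and fit diagnostics."""

    params: ModelParams
    chi2: float
    method: str
    objective_mode: str
    grid_step: float | None = None
    rmse: dict[str, float] = dc_field(default_factory=dict)
    n_evaluations: int = 0
    converged: bool = True


def field_totals(observed: pd.DataFrame) -> pd.DataFrame:
    """Normalise an observation source to per-(field, year) totals.

    Accepts either a single-year stock panel (with an ``age`` column,
    summed out) or an already-aggregated frame with columns
    ``field, year`` and ``count`` (or ``Z``).
    """
    df = observed
    value = "count" if "count" in df.columns else "Z"
    out = df.groupby(["field", "year"], as_index=False)[value].sum()
    return out.rename(columns={value: "Z"})


def _totals_lookup(observed: pd.DataFrame) -> dict[tuple[str, int], float]:
    z = field_totals(observed)
    return {(r.field, int(r.year)): float(r.Z) for r in z.itertuples()}


def _chi2_one_year(z: np.ndarray, m: np.ndarray) -> float:
    if (z <= 0).any():
        raise ValueError("observed totals must be positive in compared years")
    w = z / z.sum()
    rel = (z - m) / z
    return float(np.sum(w * rel * rel))


def chi_squared(
    run_: ModelRun, observed: pd.DataFrame, mode: str = "final_year"
) -> float:
    """Weighted chi-squared distance between model and observed totals.

    ``final_year`` evaluates ``sum_i w_i ((Z_i - M_i) / Z_i)**2`` with
    ``w_i = Z_i / sum_i Z_i`` at the last observed (non-forecast) year;
    ``all_years`` averages that expression over every observed year
    shared by run and data.
    """
    return _chi_squared_cached(run_, _totals_lookup(observed), mode)


def _chi_squared_cached(
    run_: ModelRun, lookup: dict[tuple[str, int], float], mode: str
) -> float:
    if mode not in ("final_year", "all_years"):
        raise ValueError(f"unknown objective mode {mode!r}")
    m = run_.counts.sum(axis=(2, 3))  # (year, field)

    def year_chi2(year: int) -> float:
        yi = int(np.where(run_.years == year)[0][0])
        z = np.array([lookup[(f, year)] for f in run_.fields])
        return _chi2_one_year(z, m[yi])

    if mode == "final_year":
        year = run_.last_observed_year
        missing = [f for f in run_.fields if (f, year) not in lookup]
        if missing:
            raise ValueError(f"observed totals missing for {missing} at {year}")
        return year_chi2(year)

    years = [
        int(y)
        for y, ph in zip(run_.years, run_.phases)
        if ph != "forecast" and all((f, int(y)) in lookup for f in run_.fields)
    ]
    if not years:
        raise ValueError("no overlapping observed years")
    return float(np.mean([year_chi2(y) for y in years]))


def validation_rmse(run_: ModelRun, observed: pd.DataFrame) -> dict[str, float]:
    """Per-field RMSE between model and data over validation years."""
    lookup = _totals_lookup(observed)
    m = run_.counts.sum(axis=(2, 3))
    out: dict[str, float] = {}
    for fi, f in enumerate(run_.fields):
        resid = [
            m[yi, fi] - lookup[(f, int(y))]
            for yi, (y, ph) in enumerate(zip(run_.years, run_.phases))
            if ph == "validation" and (f, int(y)) in lookup
        ]
        if len(resid) < 2:
            raise ValueError(
                f"need at least two validation years for field {f!r}, "
                f"got {len(resid)}"
            )
        out[f] = float(np.sqrt(np.mean(np.square(resid))))
    return out


def propagate_error(rmse: float | Mapping[str, float], horizon: int):
    """Forecast sigma at ``horizon`` years: ``RMSE * sqrt(h)``.

    Assumes independent annual error increments, so the propagated
    standard error grows with the square root of the horizon.
    """
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    if isinstance(rmse, Mapping):
        return {k: float(v) * float(np.sqrt(horizon)) for k, v in rmse.items()}
    return float(rmse) * float(np.sqrt(horizon))


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def calibrate_grid(
    panel: pd.DataFrame,
    gamma: pd.DataFrame | np.ndarray,
    inflow: InflowSeries,
    config: CountryConfig,
    observed: pd.DataFrame | None = None,
    objective_mode: str = "final_year",
    grid_step: float = 0.01,
    t0: int | None = None,
) -> FitResult:
    """Exhaustive search over the (p_enter, p_GP) grid.

    Both parameters range over ``0, grid_step, ..., 1``.  Ties are broken
    lexicographically (smallest ``p_enter``, then smallest first-field
    probability), which the ascending scan with strict improvement
    implements directly.
    """
    if len(config.fields) != 2:
        raise ValueError("grid calibration supports exactly two fields")
    f1, f2 = config.fields
    if observed is None:
        observed = panel
    n = int(round(1.0 / grid_step))
    values = np.arange(n + 1) / n

    g = gamma if isinstance(gamma, np.ndarray) else gamma_array(gamma)
    state0 = initialize(
        panel, config.t0 if t0 is None else t0, fields=config.fields
    )
    lookup = _totals_lookup(observed)
    best: tuple[float, ModelParams, ModelRun] | None = None
    n_eval = 0
    for pe in values:
        for pg in values:
            params = ModelParams(p_enter=float(pe), p={f1: float(pg), f2: float(1.0 - pg)})
            run_ = run(panel, params, g, inflow, config, state0=state0,
                       end_year=config.last_data_year)
            c2 = _chi_squared_cached(run_, lookup, objective_mode)
            n_eval += 1
            if best is None or c2 < best[0]:
                best = (c2, params, run_)
    assert best is not None
    chi2, params, best_run = best
    rmse = _maybe_rmse(best_run, observed)
    return FitResult(
        params=params, chi2=chi2, method="grid", objective_mode=objective_mode,
        grid_step=grid_step, rmse=rmse, n_evaluations=n_eval,
    )


def _maybe_rmse(run_: ModelRun, observed: pd.DataFrame) -> dict[str, float]:
    try:
        return validation_rmse(run_, observed)
    except ValueError:
        return {}


# ---------------------------------------------------------------------------
# projected gradient descent
# ---------------------------------------------------------------------------

def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of ``v`` onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    n = len(v)
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, n + 1) > 0)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _project(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    out[0] = min(max(out[0], 0.0), 1.0)
    out[1:] = project_simplex(out[1:])
    return out


def calibrate_gradient(
    panel: pd.DataFrame,
    gamma: pd.DataFrame | np.ndarray,
    inflow: InflowSeries,
    config: CountryConfig,
    seed: int = 0,
    observed: pd.DataFrame | None = None,
    objective_mode: str = "final_year",
    restarts: int = 5,
    max_iter: int = 300,
    tol: float = 1e-14,
    t0: int | None = None,
) -> FitResult:
    """Projected numeric-gradient descent over (p_enter, p_1..p_K).

    Central-difference gradients, backtracking line search, Euclidean
    projection of the field probabilities onto the simplex, and seeded
    random restarts.  Deterministic for a fixed seed.
    """
    fields = config.fields
    if len(fields) < 2:
        raise ValueError("need at least two fields")
    if observed is None:
        observed = panel
    g = gamma if isinstance(gamma, np.ndarray) else gamma_array(gamma)
    state0 = initialize(
        panel, config.t0 if t0 is None else t0, fields=config.fields
    )
    lookup = _totals_lookup(observed)
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        p = dict(zip(fields, x[1:]))
        params = ModelParams(p_enter=float(x[0]), p=p)
        r = run(panel, params, g, inflow, config, state0=state0,
                end_year=config.last_data_year)
        return _chi_squared_cached(r, lookup, objective_mode)

    def num_grad(x: np.ndarray, h: float = 1e-5) -> np.ndarray:
        grad = np.zeros_like(x)
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            xp, xm = _project(xp), _project(xm)
            denom = xp[i] - xm[i]
            grad[i] = (objective(xp) - objective(xm)) / denom if denom else 0.0
        return grad

    rng = np.random.default_rng(seed)
    k = len(fields)
    starts = [np.concatenate(([1.0], np.full(k, 1.0 / k)))]
    for _ in range(max(restarts - 1, 0)):
        p0 = rng.dirichlet(np.ones(k))
        starts.append(np.concatenate(([rng.uniform(0.2, 1.0)], p0)))

    best_x, best_f = None, np.inf
    converged = False
    for x in starts:
        x = _project(np.asarray(x, dtype=float))
        fx = objective(x)
        local_converged = False
        for _ in range(max_iter):
            grad = num_grad(x)
            step_size = 1.0
            improved = False
            while step_size > 1e-14:
                cand = _project(x - step_size * grad)
                fc = objective(cand)
                if fc < fx - 1e-18:
                    x, fx = cand, fc
                    improved = True
                    break
                step_size /= 2.0
            if not improved:
                local_converged = True
                break
            if fx < tol:
                local_converged = True
                break
        converged = converged or local_converged
        if fx < best_f:
            best_x, best_f = x.copy(), fx

    assert best_x is not None
    if not converged:
        warnings.warn("gradient calibration did not converge; returning best found")
    params = ModelParams(
        p_enter=float(best_x[0]), p=dict(zip(fields, map(float, best_x[1:])))
    )
    best_run = run(panel, params, g, inflow, config, state0=state0,
                   end_year=config.last_data_year)
    rmse = _maybe_rmse(best_run, observed)
    return FitResult(
        params=params, chi2=float(best_f), method="gradient",
        objective_mode=objective_mode, rmse=rmse, n_evaluations=n_eval,
        converged=converged,
    )
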