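"""Constant-density requirement curves, density gaps, significance
tests, and the pandemic demand-shock scenario.

The requirement curve anchors the physician-per-population density at
the last data year and scales it with a population scenario.  The
density gap at horizon ``T`` is the model-minus-requirement stock
difference, normalised by ``T`` times the annual inflow level, so it
reads as the fraction of annual entrants to add (gap > 0 would need
removal to hold density) per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import field_totals
from .demography import InflowSeries
from .eurostat_io import RawTable
from .supply_model import ModelRun


def attenuated_risk(r_baseline: float, attenuation: float) -> float:
    """Outpatient-care risk after attenuation: ``r_baseline * (1 - attenuation)``."""
    for name, v in (("r_baseline", r_baseline), ("attenuation", attenuation)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return r_baseline * (1.0 - attenuation)


@dataclass
class CovidShockConfig:
    """Demand-shock inputs: infection probabilities and excess-care risk.

    ``infection_prob`` maps year to the probability of infection in that
    year; years beyond the last configured year reuse its value.  The
    increased risk of needing outpatient care is ``r_baseline`` up to
    ``attenuation_from`` and ``r_baseline * (1 - attenuation)`` from then
    on.  ``hazard_ratio`` documents the source of ``r_baseline`` (an HR
    of 1.2 corresponds to a 20% increased risk).
    """

    infection_prob: dict[int, float]
    r_baseline: float = 0.20
    attenuation: float = 0.74
    attenuation_from: int = 2022
    hazard_ratio: float = 1.2

    def __post_init__(self) -> None:
        self.infection_prob = {int(k): float(v) for k, v in self.infection_prob.items()}
        if not self.infection_prob:
            raise ValueError("infection_prob must not be empty")
        for year, i in self.infection_prob.items():
            if not 0.0 <= i <= 1.0:
                raise ValueError(f"infection probability for {year} outside [0, 1]")
        # must be gap-free so carry-forward is well defined
        years = sorted(self.infection_prob)
        gaps = [y for y in range(years[0], years[-1]) if y not in self.infection_prob]
        if gaps:
            raise ValueError(f"infection_prob has gaps at {gaps}")
        attenuated_risk(self.r_baseline, self.attenuation)  # range check

    def infection(self, year: int) -> float:
        """I(t): configured value, carried forward past the last year."""
        years = sorted(self.infection_prob)
        if year < years[0]:
            return 0.0
        if year > years[-1]:
            return self.infection_prob[years[-1]]
        if year not in self.infection_prob:
            raise ValueError(f"infection probability undefined for {year}")
        return self.infection_prob[year]

    def risk(self, year: int) -> float:
        """r(t): baseline before the attenuation year, attenuated after."""
        if year >= self.attenuation_from:
            return attenuated_risk(self.r_baseline, self.attenuation)
        return self.r_baseline


def requirement_curve(
    observed: pd.DataFrame,
    population: RawTable | pd.DataFrame,
    field: str,
    anchor_year: int,
    scenario: str = "baseline",
) -> pd.DataFrame:
    """Stock needed to hold the anchor-year physician density constant.

    ``C_i(t) = Z_i(anchor) * pop(t) / pop(anchor)`` for all years of the
    population scenario at or after the anchor.  Returns a frame with
    columns ``field, scenario, year, C``.
    """
    z = field_totals(observed)
    z_anchor = z[(z["field"] == field) & (z["year"] == anchor_year)]
    if z_anchor.empty:
        raise ValueError(f"no observed stock for {field!r} at anchor {anchor_year}")
    z0 = float(z_anchor["Z"].iloc[0])

    pop = population.df if isinstance(population, RawTable) else population
    pop = pop[pop["scenario"] == scenario]
    if pop.empty:
        raise ValueError(f"population scenario {scenario!r} not found")
    pop = pop[pop["year"] >= anchor_year].sort_values("year")
    anchor_pop = pop[pop["year"] == anchor_year]
    if anchor_pop.empty:
        raise ValueError(f"population scenario {scenario!r} missing anchor {anchor_year}")
    p0 = float(anchor_pop["count"].iloc[0])
    if p0 <= 0:
        raise ValueError("anchor population must be positive")
    return pd.DataFrame(
        {
            "field": field,
            "scenario": scenario,
            "year": pop["year"].astype(int).to_numpy(),
            "C": z0 * pop["count"].to_numpy() / p0,
        }
    )


@dataclass
class DensityGap:
    """Gap at the requested horizon plus the full annual series."""

    field: str
    T: int
    year: int
    dg: float
    series: pd.DataFrame  # columns: T, year, dg


def density_gap(
    run_: ModelRun,
    curve: pd.DataFrame,
    inflow: InflowSeries,
    T: int,
) -> DensityGap:
    """Density gap ``DG(T) = (M(anchor+T) - C(anchor+T)) / (T * Y)``.

    ``Y`` is the constant forecast inflow level; the anchor is the last
    observed year of the run.  The annual series covers every horizon
    from 1 to the end of both the run and the curve.
    """
    if T < 1:
        raise ValueError("horizon T must be >= 1")
    y = inflow.forecast_level
    if y <= 0:
        raise ValueError("forecast inflow level must be positive")
    field = str(curve["field"].iloc[0])
    anchor = run_.last_observed_year
    m = run_.total_series(field)
    c = curve.set_index("year")["C"]
    horizons = []
    t_max = int(min(m.index.max(), c.index.max())) - anchor
    if T > t_max:
        raise ValueError(f"horizon T={T} exceeds available forecast ({t_max} years)")
    for t in range(1, t_max + 1):
        year = anchor + t
        horizons.append(
            {"T": t, "year": year,
             "dg": (float(m.loc[year]) - float(c.loc[year])) / (t * y)}
        )
    series = pd.DataFrame.from_records(horizons)
    dg = float(series.loc[series["T"] == T, "dg"].iloc[0])
    return DensityGap(field=field, T=T, year=anchor + T, dg=dg, series=series)


def gap_significance(dg: float, sigma_dg: float, n_tests: int = 1) -> float:
    """Two-sided normal p-value for DG != 0, Bonferroni-corrected.

    ``p = min(1, n_tests * 2 * (1 - Phi(|DG| / sigma_DG)))``.
    """
    if sigma_dg <= 0:
        raise ValueError("sigma_dg must be positive")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p = 2.0 * stats.norm.sf(abs(dg) / sigma_dg)
    return float(min(1.0, n_tests * p))


@dataclass
class CovidShockResult:
    """Shocked requirement curve and its summary deltas."""

    shocked_curve: pd.DataFrame
    additional_per_year: float
    delta_dg: float | None = None


def covid_shock(
    curve: pd.DataFrame,
    shock: CovidShockConfig,
    run_: ModelRun | None = None,
    inflow: InflowSeries | None = None,
    T: int | None = None,
) -> CovidShockResult:
    """Inflate the requirement curve by the pandemic demand factor.

    ``C_shocked(t) = C(t) * (1 + I(t) * r(t))``.  The additional
    physicians per year are the mean excess requirement over years after
    the anchor (the curve's first year).  When a model run, inflow and
    horizon are supplied, the absolute change in the density gap is
    computed as well.
    """
    out = curve.copy()
    anchor = int(out["year"].min())
    factors = np.array(
        [
            1.0 + shock.infection(int(t)) * shock.risk(int(t))
            if int(t) > anchor
            else 1.0
            for t in out["year"]
        ]
    )
    out["C"] = out["C"].to_numpy() * factors
    after = out["year"] > anchor
    additional = float((out.loc[after, "C"].to_numpy()
                        - curve.loc[after, "C"].to_numpy()).mean())

    delta = None
    if run_ is not None and inflow is not None and T is not None:
        base = density_gap(run_, curve, inflow, T)
        shocked = density_gap(run_, out, inflow, T)
        delta = abs(shocked.dg - base.dg)
    return CovidShockResult(
        shocked_curve=out, additional_per_year=additional, delta_dg=delta
    )
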