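"""Three-phase orchestration (calibrate, validate, forecast) per country
and batch runs across countries with failure isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import calibration, demography, outcomes
from .calibration import FitResult, field_totals
from .demography import InflowSeries
from .eurostat_io import CountryConfig, RawTable, select_calibration_start
from .outcomes import CovidShockConfig
from .supply_model import ModelRun, run as run_model

logger = logging.getLogger(__name__)

ALL_FIELDS_LABEL = "all"


@dataclass
class RunSettings:
    """Cross-country options for a batch run."""

    method: str = "grid"  # "grid" or "gradient"
    objective_mode: str = "final_year"
    seed: int = 0
    covid: CovidShockConfig | None = None
    scenarios: tuple[str, ...] | None = None  # None: every scenario in the data
    n_tests: int | None = None  # None: inferred from the batch size

    def __post_init__(self) -> None:
        if self.method not in ("grid", "gradient"):
            raise ValueError("method must be 'grid' or 'gradient'")
        if self.objective_mode not in ("final_year", "all_years"):
            raise ValueError("objective_mode must be 'final_year' or 'all_years'")


@dataclass
class Reference:
    """Pooled fallback quantities for countries without age/sex stocks."""

    exit_rates: pd.DataFrame
    age_distribution: pd.DataFrame  # sex, age, share


@dataclass
class CountryResult:
    country: str
    t0: int
    fit: FitResult
    run: ModelRun
    gaps: pd.DataFrame
    exit_rates: pd.DataFrame
    inflow: InflowSeries


def _split_panel_by_field(
    panel_all: pd.DataFrame,
    totals: pd.DataFrame,
    fields: tuple[str, ...],
    t0: int,
) -> pd.DataFrame:
    """Per-field t0 slice by splitting the all-physician pyramid.

    Age/sex structure is only reported for all physicians combined, so
    the initial per-field stocks take the pooled pyramid scaled by each
    field's share of the total stock at t0.
    """
    z = field_totals(totals)
    z0 = {f: float(z[(z["field"] == f) & (z["year"] == t0)]["Z"].sum()) for f in fields}
    total = sum(z0.values())
    if total <= 0:
        raise ValueError(f"zero total field stock at t0={t0}")
    sl = panel_all[panel_all["year"] == t0]
    if sl.empty:
        raise ValueError(f"no age/sex stocks at t0={t0}")
    # rescale the pyramid so its total matches the field table's total:
    # the two tables may disagree slightly (noise, rounding)
    pyramid_total = sl["count"].sum()
    if pyramid_total <= 0:
        raise ValueError(f"zero age/sex stock at t0={t0}")
    parts = []
    for f in fields:
        part = sl.copy()
        part["field"] = f
        part["count"] = part["count"] * (z0[f] / pyramid_total)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def _panel_from_reference(
    reference: Reference, totals: pd.DataFrame, country: str, t0: int
) -> pd.DataFrame:
    """Build an all-physician t0 pyramid from the reference distribution."""
    z = field_totals(totals)
    total = float(z[z["year"] == t0]["Z"].sum())
    if total <= 0:
        raise ValueError(f"zero total stock at t0={t0}")
    dist = reference.age_distribution.copy()
    dist["country"] = country
    dist["field"] = ALL_FIELDS_LABEL
    dist["year"] = t0
    dist["count"] = dist["share"] * total
    return dist[["country", "field", "sex", "age", "year", "count"]]


def run_country(
    tables: dict[str, RawTable],
    config: CountryConfig,
    settings: RunSettings | None = None,
    reference: Reference | None = None,
) -> CountryResult:
    """Full pipeline for one country: read slices, estimate rates,
    calibrate, simulate, and score density gaps.

    Countries lacking an age/sex stock table fall back to the supplied
    reference exit rates and age distribution.
    """
    settings = settings or RunSettings()
    for kind in ("stocks_by_field", "graduates", "population_projection"):
        if kind not in tables:
            raise ValueError(f"required table {kind!r} missing for {config.country}")
    totals_table = tables["stocks_by_field"].df
    totals_table = totals_table[totals_table["field"].isin(config.fields)]
    if set(totals_table["field"].unique()) != set(config.fields):
        raise ValueError(
            f"{config.country}: stocks_by_field must cover fields {config.fields}"
        )

    has_age_sex = "stocks_by_age_sex" in tables
    if has_age_sex:
        t0 = config.t0 or select_calibration_start(
            tables["stocks_by_age_sex"], config
        )
        panel_all = demography.interpolate_panel(tables["stocks_by_age_sex"])
        panel_all = panel_all[panel_all["year"] >= t0]
        net = demography.compute_net_rates(panel_all, ALL_FIELDS_LABEL)
        ref_rates = reference.exit_rates if reference is not None else None
        exit_rates = demography.estimate_exit_rates(net, reference=ref_rates)
        sex_split = demography.entrant_sex_split(panel_all, config.last_data_year)
    else:
        if reference is None:
            raise ValueError(
                f"{config.country}: no age/sex stocks and no reference supplied"
            )
        t0 = config.t0 or min(
            int(y) for y in totals_table["year"].unique()
            if not config.breaks or y > max(config.breaks)
        )
        panel_all = _panel_from_reference(reference, totals_table, config.country, t0)
        exit_rates = reference.exit_rates
        by_sex = panel_all[panel_all["age"].between(25, 34)].groupby("sex")["count"].sum()
        tot = float(by_sex.sum())
        sex_split = (float(by_sex.get("F", 0.0)) / tot, float(by_sex.get("M", 0.0)) / tot)

    inflow = demography.build_inflow(
        tables["graduates"], tables.get("migrants"), sex_split=sex_split
    )
    if config.inflow_mode == "last3":
        observed_years = sorted(inflow.years)
        window = (observed_years[-3], observed_years[-1])
    else:
        window = config.inflow_window
    inflow.forecast_level = demography.estimate_inflow(inflow, window)

    panel_fields = _split_panel_by_field(panel_all, totals_table, config.fields, t0)

    if settings.method == "grid":
        fit = calibration.calibrate_grid(
            panel_fields, exit_rates, inflow, config,
            observed=totals_table, objective_mode=settings.objective_mode, t0=t0,
        )
    else:
        fit = calibration.calibrate_gradient(
            panel_fields, exit_rates, inflow, config,
            seed=settings.seed, observed=totals_table,
            objective_mode=settings.objective_mode, t0=t0,
        )

    run_ = run_model(panel_fields, fit.params, exit_rates, inflow, config, t0=t0)
    gaps = _gap_report(run_, totals_table, tables["population_projection"],
                       inflow, fit, config, settings)
    return CountryResult(
        country=config.country, t0=t0, fit=fit, run=run_, gaps=gaps,
        exit_rates=exit_rates, inflow=inflow,
    )


def _gap_report(
    run_: ModelRun,
    totals: pd.DataFrame,
    population: RawTable,
    inflow: InflowSeries,
    fit: FitResult,
    config: CountryConfig,
    settings: RunSettings,
) -> pd.DataFrame:
    """Table-1-style rows: one per field plus an all-fields aggregate."""
    anchor = config.last_data_year
    T = config.forecast_end - anchor
    scenarios = settings.scenarios or tuple(
        sorted(population.df["scenario"].unique())
    )
    if "baseline" not in scenarios:
        raise ValueError("a 'baseline' population scenario is required")

    # aggregate observed totals and model series for the "all" row
    totals_all = totals.groupby("year", as_index=False)["count"].sum()
    totals_all["field"] = ALL_FIELDS_LABEL
    obs = pd.concat([totals, totals_all], ignore_index=True)

    rows = []
    report_fields = list(config.fields) + [ALL_FIELDS_LABEL]
    for f in report_fields:
        if f == ALL_FIELDS_LABEL:
            rmse = float(np.sqrt(np.sum(np.square(list(fit.rmse.values()))))) \
                if fit.rmse else np.nan
            m_series = sum(run_.total_series(g) for g in config.fields)
        else:
            rmse = fit.rmse.get(f, np.nan)
            m_series = run_.total_series(f)

        dgs = {}
        for scen in scenarios:
            curve = outcomes.requirement_curve(obs, population, f, anchor, scen)
            c = curve.set_index("year")["C"]
            year = anchor + T
            dgs[scen] = (float(m_series.loc[year]) - float(c.loc[year])) / (
                T * inflow.forecast_level
            )
        dg = dgs["baseline"]
        sigma_dg = (
            calibration.propagate_error(rmse, T) / (T * inflow.forecast_level)
            if np.isfinite(rmse) and rmse > 0
            else np.nan
        )
        p = (
            outcomes.gap_significance(dg, sigma_dg, n_tests=settings.n_tests or 1)
            if np.isfinite(sigma_dg)
            else np.nan
        )
        row = {
            "country": config.country, "field": f, "T": T,
            "dg": dg, "sigma_dg": sigma_dg, "p_value": p,
            "dg_min": min(dgs.values()), "dg_max": max(dgs.values()),
        }
        if settings.covid is not None:
            curve = outcomes.requirement_curve(obs, population, f, anchor, "baseline")
            shock = outcomes.covid_shock(curve, settings.covid)
            shocked = shock.shocked_curve.set_index("year")["C"]
            year = anchor + T
            dg_shocked = (float(m_series.loc[year]) - float(shocked.loc[year])) / (
                T * inflow.forecast_level
            )
            row["covid_additional_per_year"] = shock.additional_per_year
            row["covid_delta_dg"] = abs(dg_shocked - dg)
        rows.append(row)
    return pd.DataFrame.from_records(rows)


@dataclass
class BatchResult:
    results: dict[str, CountryResult]
    failures: dict[str, str]
    table: pd.DataFrame
    reference: Reference | None = None


def build_reference(
    items: dict[str, dict[str, RawTable]],
    configs: dict[str, CountryConfig],
) -> Reference | None:
    """Pooled exit rates and age distribution from complete countries."""
    panels = []
    ref_year = None
    for country, tables in items.items():
        if "stocks_by_age_sex" not in tables:
            continue
        try:
            panel = demography.interpolate_panel(tables["stocks_by_age_sex"])
        except ValueError:
            continue
        panels.append(panel)
        ref_year = max(ref_year or 0, configs[country].last_data_year)
    if not panels:
        return None
    rates = demography.reference_exit_rates(panels)
    dist = demography.reference_age_distribution(panels, ref_year)
    return Reference(exit_rates=rates, age_distribution=dist)


def run_batch(
    items: dict[str, dict[str, RawTable]],
    configs: dict[str, CountryConfig],
    settings: RunSettings | None = None,
) -> BatchResult:
    """Run every country, isolating per-country failures.

    Bonferroni ``n_tests`` defaults to the number of density-gap
    hypotheses in the batch (countries x (fields + all)); p-values in
    the combined table are corrected with it.
    """
    settings = settings or RunSettings()
    reference = build_reference(items, configs)
    results: dict[str, CountryResult] = {}
    failures: dict[str, str] = {}
    for country in sorted(items):
        try:
            results[country] = run_country(
                items[country], configs[country], settings, reference=reference
            )
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            logger.error("country %s failed: %s", country, exc)
            failures[country] = str(exc)

    gap_frames = [r.gaps for _, r in sorted(results.items())]
    if gap_frames:
        table = pd.concat(gap_frames, ignore_index=True)
        n_tests = settings.n_tests or len(table)
        table["n_tests"] = n_tests
        table["p_value"] = [
            outcomes.gap_significance(dg, sd, n_tests=n_tests)
            if np.isfinite(sd) and sd > 0
            else np.nan
            for dg, sd in zip(table["dg"], table["sigma_dg"])
        ]
    else:
        table = pd.DataFrame()
    return BatchResult(results=results, failures=failures, table=table,
                       reference=reference)
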