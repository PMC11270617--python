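"""Generator for EUROSTAT-shaped country panels with known ground truth.

Every other module is tested against panels produced here: the
generator runs the actual simulation core forward from a parametric
initial pyramid under known parameters, then degrades the output into
the five tidy table kinds (age-grouped stocks, field totals, graduates,
migrants, population projections), optionally with multiplicative
log-normal observation noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import AGES, EXIT_AGES, InflowSeries
from .eurostat_io import (
    MODEL_AGE_GROUPS,
    SEXES,
    CountryConfig,
    RawTable,
    make_table,
    write_table,
)
from .supply_model import ModelParams, ModelState, gamma_array, run


def generate_exit_curve(
    age_half: float, steepness: float, plateau: float, ages: np.ndarray = EXIT_AGES
) -> np.ndarray:
    """Logistic exit-hazard curve over ``ages``.

    ``gamma(a) = plateau / (1 + exp(-steepness * (a - age_half)))`` —
    near zero well below ``age_half``, half the plateau at ``age_half``,
    approaching ``plateau`` beyond it.
    """
    if not 0.0 <= plateau <= 1.0:
        raise ValueError("plateau must lie in [0, 1]")
    a = np.asarray(ages, dtype=float)
    return plateau / (1.0 + np.exp(-steepness * (a - age_half)))


@dataclass
class SyntheticSpec:
    """Ground-truth configuration for one synthetic country."""

    seed: int = 0
    country: str = "SX"
    start_year: int = 2000
    last_data_year: int = 2019
    forecast_end: int = 2040
    fields: tuple[str, ...] = ("GP", "specialist")
    field_shares: tuple[float, ...] = (0.3, 0.7)
    p_enter: float = 0.9
    p_fields: tuple[float, ...] = (0.3, 0.7)
    # logistic exit hazard
    exit_age_half: float = 62.0
    exit_steepness: float = 0.5
    exit_plateau: float = 0.35
    # inflow trajectory
    inflow_level: float = 160.0
    inflow_trend: float = 0.0
    inflow_noise_sd: float = 0.0
    graduate_share: float = 0.85
    inflow_window: tuple[int, int] = (2014, 2019)
    # initial pyramid
    initial_total: float = 5000.0
    mean_age: float = 45.0
    age_spread: float = 10.0
    female_share: float = 0.55
    # population
    population0: float = 1_000_000.0
    pop_growth: dict[str, float] = dc_field(
        default_factory=lambda: {"baseline": 0.002, "high": 0.006, "low": -0.003}
    )
    # multiplicative log-normal observation noise on reported counts
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.initial_total <= 0:
            raise ValueError("initial_total must be positive")
        if len(self.fields) != len(self.field_shares) or len(self.fields) != len(
            self.p_fields
        ):
            raise ValueError("fields, field_shares and p_fields must align")
        for name in ("p_enter", "exit_plateau", "female_share", "graduate_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.inflow_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if "baseline" not in self.pop_growth:
            raise ValueError("a 'baseline' population scenario is required")

    @property
    def true_params(self) -> ModelParams:
        return ModelParams(
            p_enter=self.p_enter, p=dict(zip(self.fields, self.p_fields))
        )

    def country_config(self) -> CountryConfig:
        return CountryConfig(
            country=self.country,
            t0=self.start_year,
            last_data_year=self.last_data_year,
            forecast_end=self.forecast_end,
            fields=self.fields,
            inflow_window=self.inflow_window,
        )


@dataclass
class SyntheticPanel:
    """Generated tables plus the exact quantities used to generate them."""

    spec: SyntheticSpec
    tables: dict[str, RawTable]
    truth_panel: pd.DataFrame  # single-year stocks: field, sex, age, year, count
    truth_gamma: pd.DataFrame  # sex, age, gamma
    truth_inflow: InflowSeries
    truth_params: ModelParams

    def truth_sidecar(self) -> dict:
        """JSON-compatible summary of the ground truth."""
        return {
            "spec": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.spec).items()
            },
            "params": {
                "p_enter": self.truth_params.p_enter,
                "p": dict(self.truth_params.p),
            },
            "inflow_forecast_level": self.truth_inflow.forecast_level,
            "sex_split": list(self.truth_inflow.sex_split),
        }


def _initial_state(spec: SyntheticSpec) -> ModelState:
    weights = np.exp(-0.5 * ((AGES - spec.mean_age) / spec.age_spread) ** 2)
    weights = weights / weights.sum()
    sex_shares = np.array([spec.female_share, 1.0 - spec.female_share])
    counts = (
        np.asarray(spec.field_shares)[:, None, None]
        * sex_shares[None, :, None]
        * weights[None, None, :]
        * spec.initial_total
    )
    return ModelState(
        year=spec.start_year, fields=spec.fields, counts=counts
    )


def _truth_gamma_table(spec: SyntheticSpec) -> pd.DataFrame:
    curve = generate_exit_curve(
        spec.exit_age_half, spec.exit_steepness, spec.exit_plateau
    )
    recs = [
        {"sex": s, "age": int(a), "gamma": float(g)}
        for s in SEXES
        for a, g in zip(EXIT_AGES, curve)
    ]
    return pd.DataFrame.from_records(recs)


def _group_label(age: int) -> str:
    for grp in MODEL_AGE_GROUPS:
        lo, hi = grp.split("-")
        if int(lo) <= age <= int(hi):
            return grp
    raise ValueError(f"age {age} outside modelled groups")


def generate_panel(spec: SyntheticSpec) -> SyntheticPanel:
    """Run the simulation core under the spec and emit all five tables.

    Deterministic for a fixed seed: identical specs produce
    byte-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    cfg = spec.country_config()

    # observed annual inflow, years t0+1 .. last_data_year
    years_in = np.arange(spec.start_year + 1, spec.last_data_year + 1)
    totals = spec.inflow_level + spec.inflow_trend * (years_in - years_in[0])
    if spec.inflow_noise_sd > 0:
        totals = totals * np.exp(
            rng.normal(0.0, spec.inflow_noise_sd, size=len(totals))
        )
    totals = np.clip(totals, 0.0, None)
    inflow = InflowSeries(
        years=years_in,
        graduates=totals * spec.graduate_share,
        migrants=totals * (1.0 - spec.graduate_share),
        sex_split=(spec.female_share, 1.0 - spec.female_share),
    )
    lo, hi = spec.inflow_window
    inflow.forecast_level = float(
        totals[(years_in >= lo) & (years_in <= hi)].mean()
    )

    gamma = _truth_gamma_table(spec)
    state0 = _initial_state(spec)
    run_ = run(None, spec.true_params, gamma, inflow, cfg, state0=state0)

    # ground-truth single-year panel over the data window
    recs = []
    for yi, year in enumerate(run_.years):
        if year > spec.last_data_year:
            break
        for fi, f in enumerate(spec.fields):
            for si, s in enumerate(SEXES):
                for ai, a in enumerate(AGES):
                    recs.append(
                        {"country": spec.country, "field": f, "sex": s,
                         "age": int(a), "year": int(year),
                         "count": float(run_.counts[yi, fi, si, ai])}
                    )
    truth_panel = pd.DataFrame.from_records(recs)

    def noisy(values: np.ndarray) -> np.ndarray:
        if spec.noise_sd <= 0:
            return values
        return values * np.exp(rng.normal(0.0, spec.noise_sd, size=values.shape))

    # stocks_by_age_sex: all fields aggregated, 10-year groups
    grouped = truth_panel.copy()
    grouped["age_group"] = grouped["age"].map(_group_label)
    grouped = grouped.groupby(
        ["country", "year", "sex", "age_group"], as_index=False
    )["count"].sum()
    grouped["count"] = noisy(grouped["count"].to_numpy())
    stocks_age = make_table(grouped, "stocks_by_age_sex")

    # stocks_by_field: per-field totals per year
    by_field = truth_panel.groupby(
        ["country", "year", "field"], as_index=False
    )["count"].sum()
    by_field["count"] = noisy(by_field["count"].to_numpy())
    stocks_field = make_table(by_field, "stocks_by_field")

    grads = make_table(
        pd.DataFrame(
            {"country": spec.country, "year": years_in, "count": inflow.graduates}
        ),
        "graduates",
    )
    migr = make_table(
        pd.DataFrame(
            {"country": spec.country, "year": years_in, "count": inflow.migrants}
        ),
        "migrants",
    )

    pop_recs = []
    pop_years = np.arange(spec.start_year, spec.forecast_end + 1)
    base_g = spec.pop_growth["baseline"]
    for scen, g in sorted(spec.pop_growth.items()):
        pop = spec.population0
        for year in pop_years:
            pop_recs.append(
                {"country": spec.country, "scenario": scen,
                 "year": int(year), "count": pop}
            )
            rate = base_g if year < spec.last_data_year else g
            pop = pop * (1.0 + rate)
    population = make_table(pd.DataFrame.from_records(pop_recs),
                            "population_projection")

    return SyntheticPanel(
        spec=spec,
        tables={
            "stocks_by_age_sex": stocks_age,
            "stocks_by_field": stocks_field,
            "graduates": grads,
            "migrants": migr,
            "population_projection": population,
        },
        truth_panel=truth_panel,
        truth_gamma=gamma,
        truth_inflow=inflow,
        truth_params=spec.true_params,
    )


def write_panel(panel: SyntheticPanel, out_dir: str | Path) -> dict[str, Path]:
    """Write the five tables plus a ground-truth sidecar to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for kind, table in panel.tables.items():
        path = out_dir / f"{kind}.csv"
        write_table(table, path)
        paths[kind] = path
    sidecar = out_dir / "truth.json"
    sidecar.write_text(json.dumps(panel.truth_sidecar(), indent=2, sort_keys=True))
    paths["truth"] = sidecar
    return paths
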