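"""Deterministic simulation core: ageing, exit, and entry of physicians.

Stocks are continuous (real-valued) head-counts held on a dense grid
``(field, sex, age)``.  One step advances the model by one calendar
year:

``N_i(s, a+1, t+1) = (1 - gamma(s, a)) * N_i(s, a, t)
                     + p_enter * p_i * Y(s, a+1, t+1)``

The age-25 cells receive only the entry term; stock ageing out of the
last modelled age (74) leaves the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import AGES, InflowSeries
from .eurostat_io import SEXES, CountryConfig

PHASES = ("calibration", "validation", "forecast")


@dataclass(frozen=True)
class ModelParams:
    """Entry probability and field-choice probabilities.

    ``p`` maps field label to the probability a new entrant chooses that
    field; the probabilities must form a distribution.
    """

    p_enter: float
    p: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_enter <= 1.0:
            raise ValueError(f"p_enter must be in [0, 1], got {self.p_enter}")
        vals = np.array(list(self.p.values()), dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("field probabilities must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"field probabilities must sum to 1, got {vals.sum()}")

    def p_vector(self, fields: Sequence[str]) -> np.ndarray:
        return np.array([self.p[f] for f in fields], dtype=float)


@dataclass
class ModelState:
    """Stocks at one point in time on a (field, sex, age) grid."""

    year: int
    fields: tuple[str, ...]
    counts: np.ndarray  # shape (n_fields, n_sexes, n_ages)
    sexes: tuple[str, ...] = SEXES
    ages: np.ndarray = dc_field(default_factory=lambda: AGES.copy())

    def __post_init__(self) -> None:
        self.fields = tuple(self.fields)
        self.ages = np.asarray(self.ages, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        expect = (len(self.fields), len(self.sexes), len(self.ages))
        if self.counts.shape != expect:
            raise ValueError(f"counts shape {self.counts.shape} != {expect}")
        if (self.counts < 0).any():
            raise ValueError("stocks must be nonnegative")
        if not np.isfinite(self.counts).all():
            raise ValueError("stocks must be finite")

    def total(self, field: str | None = None) -> float:
        if field is None:
            return float(self.counts.sum())
        return float(self.counts[self.fields.index(field)].sum())


@dataclass
class ModelRun:
    """Yearly states plus per-field totals with phase labels."""

    fields: tuple[str, ...]
    years: np.ndarray
    counts: np.ndarray  # shape (n_years, n_fields, n_sexes, n_ages)
    phases: tuple[str, ...]
    sexes: tuple[str, ...] = SEXES
    ages: np.ndarray = dc_field(default_factory=lambda: AGES.copy())
    country: str = ""

    def totals(self) -> pd.DataFrame:
        """Tidy per-field totals ``M_i(t)`` with phase labels."""
        recs = []
        m = self.counts.sum(axis=(2, 3))  # (year, field)
        for yi, year in enumerate(self.years):
            for fi, f in enumerate(self.fields):
                recs.append(
                    {"country": self.country, "field": f, "year": int(year),
                     "phase": self.phases[yi], "M": float(m[yi, fi])}
                )
        return pd.DataFrame.from_records(recs)

    def total_series(self, field: str) -> pd.Series:
        fi = self.fields.index(field)
        return pd.Series(
            self.counts[:, fi].sum(axis=(1, 2)), index=self.years, name=field
        )

    def state(self, year: int) -> ModelState:
        yi = int(np.where(self.years == year)[0][0])
        return ModelState(
            year=int(year), fields=self.fields, counts=self.counts[yi].copy(),
            sexes=self.sexes, ages=self.ages,
        )

    @property
    def last_observed_year(self) -> int:
        obs = [int(y) for y, ph in zip(self.years, self.phases) if ph != "forecast"]
        if not obs:
            raise ValueError("run contains no observed years")
        return max(obs)


def gamma_array(
    gamma: pd.DataFrame,
    sexes: Sequence[str] = SEXES,
    ages: np.ndarray = AGES,
) -> np.ndarray:
    """Exit-rate table -> dense array of shape (n_sexes, n_ages - 1).

    Entry ``[si, ai]`` is the exit probability applied on the transition
    from ``ages[ai]`` to ``ages[ai + 1]``.
    """
    lookup = {(r.sex, int(r.age)): float(r.gamma) for r in gamma.itertuples()}
    out = np.empty((len(sexes), len(ages) - 1))
    for si, s in enumerate(sexes):
        for ai, a in enumerate(ages[:-1]):
            try:
                out[si, ai] = lookup[(s, int(a))]
            except KeyError:
                raise ValueError(f"gamma undefined for (sex={s}, age={a})") from None
    return out


def _entry_profile(
    inflow: InflowSeries, sexes: Sequence[str], ages: np.ndarray
) -> np.ndarray:
    """Per-unit-inflow entry weights, shape (n_sexes, n_ages).

    The annual total is split by sex and spread uniformly over the
    entry ages; weights sum to 1.
    """
    lo, hi = inflow.entry_age_range
    mask = (ages >= lo) & (ages <= hi)
    n_entry = int(mask.sum())
    if n_entry == 0:
        raise ValueError(f"no modelled age falls in entry range {lo}-{hi}")
    split = dict(zip(("F", "M"), inflow.sex_split))
    w = np.zeros((len(sexes), len(ages)))
    for si, s in enumerate(sexes):
        w[si, mask] = split.get(s, 0.0) / n_entry
    return w


def initialize(panel: pd.DataFrame, t0: int, fields: Sequence[str] | None = None,
               ages: np.ndarray = AGES) -> ModelState:
    """Set the initial state equal to the data slice at ``t0``.

    ``panel`` is a tidy single-year frame (field, sex, age, year, count).
    A field present in ``fields`` but absent from the data gets zero
    stocks; a partially covered (field, sex) slice is an error.
    """
    sl = panel[panel["year"] == t0]
    if sl.empty:
        raise ValueError(f"panel has no rows for t0={t0}")
    if fields is None:
        fields = tuple(sorted(sl["field"].unique()))
    fields = tuple(fields)
    ages = np.asarray(ages, dtype=int)
    counts = np.zeros((len(fields), len(SEXES), len(ages)))
    idx = {(r.field, r.sex, int(r.age)): float(r.count) for r in sl.itertuples()}
    for fi, f in enumerate(fields):
        present = [k for k in idx if k[0] == f]
        if not present:
            continue  # empty field: zero stocks, no error
        for si, s in enumerate(SEXES):
            missing = [int(a) for a in ages if (f, s, int(a)) not in idx]
            if missing:
                raise ValueError(
                    f"incomplete t0 slice for field={f!r} sex={s}: "
                    f"missing ages {missing[:5]}{'...' if len(missing) > 5 else ''}"
                )
            counts[fi, si] = [idx[(f, s, int(a))] for a in ages]
    return ModelState(year=int(t0), fields=fields, counts=counts, ages=ages)


def _update(
    counts: np.ndarray,
    g: np.ndarray,
    entry_weights: np.ndarray,
    y_total: float,
    p_enter: float,
    p_vec: np.ndarray,
) -> np.ndarray:
    """One-year update kernel shared by :func:`step` and :func:`run`."""
    new = np.zeros_like(counts)
    new[:, :, 1:] = (1.0 - g)[None, :, :] * counts[:, :, :-1]
    new += (p_enter * y_total) * p_vec[:, None, None] * entry_weights[None, :, :]
    return new


def step(
    state: ModelState,
    params: ModelParams,
    gamma: pd.DataFrame | np.ndarray,
    inflow: InflowSeries,
    y_total: float | None = None,
) -> ModelState:
    """Advance the model one year (age, exit, enter).

    ``y_total`` overrides the annual inflow looked up from ``inflow``;
    :func:`run` uses it to force the forecast level beyond the data.
    """
    g = gamma if isinstance(gamma, np.ndarray) else gamma_array(
        gamma, state.sexes, state.ages
    )
    if ((g < 0) | (g > 1)).any():
        raise ValueError("exit rates must lie in [0, 1]")
    t_next = state.year + 1
    if y_total is None:
        y_total = inflow.y(t_next)
    new = _update(
        state.counts, g, _entry_profile(inflow, state.sexes, state.ages),
        y_total, params.p_enter, params.p_vector(state.fields),
    )
    return ModelState(
        year=t_next, fields=state.fields, counts=new,
        sexes=state.sexes, ages=state.ages,
    )


def run(
    panel: pd.DataFrame,
    params: ModelParams,
    gamma: pd.DataFrame | np.ndarray,
    inflow: InflowSeries,
    config: CountryConfig,
    t0: int | None = None,
    state0: ModelState | None = None,
    end_year: int | None = None,
) -> ModelRun:
    """Iterate the yearly update from the calibration start to the horizon.

    Observed annual inflow is used through ``config.last_data_year``;
    afterwards the inflow falls back to ``inflow.forecast_level``.  Years
    are labelled ``calibration`` (t0), ``validation`` (through the last
    data year) and ``forecast``.  ``state0`` lets callers reuse a
    pre-built initial state and ``end_year`` stops the run early; the
    calibration loop uses both.
    """
    if state0 is not None:
        state, t0 = state0, state0.year
    else:
        t0 = config.t0 if t0 is None else t0
        if t0 is None:
            raise ValueError("calibration start year t0 is not set")
        state = initialize(panel, t0, fields=config.fields)
    g = gamma if isinstance(gamma, np.ndarray) else gamma_array(
        gamma, state.sexes, state.ages
    )
    if ((g < 0) | (g > 1)).any():
        raise ValueError("exit rates must lie in [0, 1]")
    entry_weights = _entry_profile(inflow, state.sexes, state.ages)
    p_vec = params.p_vector(state.fields)
    end_year = config.forecast_end if end_year is None else end_year
    years = list(range(t0, end_year + 1))
    counts = np.empty((len(years), *state.counts.shape))
    counts[0] = state.counts
    current = state.counts
    for i, t in enumerate(years[1:], start=1):
        y = inflow.y(t) if t <= config.last_data_year else inflow.forecast_level
        current = _update(current, g, entry_weights, y, params.p_enter, p_vec)
        counts[i] = current
    phases = tuple(
        "calibration" if t == t0
        else "validation" if t <= config.last_data_year
        else "forecast"
        for t in years
    )
    return ModelRun(
        fields=state.fields, years=np.array(years, dtype=int), counts=counts,
        phases=phases, sexes=state.sexes, ages=state.ages,
        country=config.country,
    )
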