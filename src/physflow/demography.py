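"""Age-structure estimation: single-year interpolation, net rates of
change, effective exit rates, and inflow summaries.

Conventions
-----------
* Modelled single-year ages run 25-74 inclusive.  Input groups ``<25``
  and ``75+`` are outside this range and dropped with a warning; stock
  ageing out of 74 leaves the model (forced exit).
* The net rate of change ``alpha(s, a, t)`` compares the cohort of age
  ``a`` in year ``t`` with the cohort of age ``a + 1`` in year ``t + 1``.
* The effective exit rate ``gamma(s, a)`` is stored as a *nonnegative*
  magnitude, so the survival factor ``(1 - gamma)`` shrinks a cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .eurostat_io import MODEL_AGE_GROUPS, SEXES, RawTable

logger = logging.getLogger(__name__)

#: Modelled single-year ages (inclusive bounds 25 and 74).
AGES: np.ndarray = np.arange(25, 75)

#: Ages at which an exit rate is defined: the transition a -> a+1 needs
#: both endpoints inside the modelled range, so 74 is excluded.
EXIT_AGES: np.ndarray = np.arange(25, 74)

#: Entry age range for new physicians (graduates and migrants).
ENTRY_AGE_RANGE: tuple[int, int] = (25, 34)

_GROUP_BOUNDS: dict[str, tuple[int, int]] = {
    "25-34": (25, 34),
    "35-44": (35, 44),
    "45-54": (45, 54),
    "55-64": (55, 64),
    "65-74": (65, 74),
}
_GROUP_MIDS = np.array([(lo + hi) / 2.0 for lo, hi in _GROUP_BOUNDS.values()])


# ---------------------------------------------------------------------------
# single-year interpolation
# ---------------------------------------------------------------------------

def interpolate_age_groups(group_counts: Mapping[str, float]) -> np.ndarray:
    """Spread 10-year group totals over single-year ages 25-74.

    The per-age profile is piecewise linear between adjacent group means
    (each anchored at the group's mid-age), flat beyond the first and
    last mid-ages, clipped at zero, and finally rescaled within each
    group so the 10 per-age counts sum exactly to the group total.

    Parameters
    ----------
    group_counts
        Mapping from the five modelled group labels to totals.

    Returns
    -------
    numpy.ndarray
        Counts for ages 25..74 (length 50).
    """
    missing = [g for g in MODEL_AGE_GROUPS if g not in group_counts]
    if missing:
        raise ValueError(f"missing age group(s) {missing}")
    totals = np.array([float(group_counts[g]) for g in MODEL_AGE_GROUPS])
    if (totals < 0).any():
        raise ValueError("group totals must be nonnegative")

    means = totals / 10.0
    raw = np.interp(AGES, _GROUP_MIDS, means)  # flat beyond end mid-ages
    raw = np.clip(raw, 0.0, None)

    out = np.empty_like(raw)
    for (lo, hi), total in zip(_GROUP_BOUNDS.values(), totals):
        sl = slice(lo - 25, hi - 25 + 1)
        block = raw[sl]
        s = block.sum()
        out[sl] = block * (total / s) if s > 0 else 0.0
    return out


def interpolate_panel(table: RawTable, field: str = "all") -> pd.DataFrame:
    """Convert an age-grouped stocks table into a single-year panel.

    Returns a tidy frame with columns ``country, field, sex, age, year,
    count`` covering ages 25-74 for every (sex, year) present.  Groups
    outside the modelled range are dropped.
    """
    if table.kind != "stocks_by_age_sex":
        raise ValueError("interpolate_panel expects a stocks_by_age_sex table")
    df = table.df
    dropped = sorted(set(df["age_group"]) - set(MODEL_AGE_GROUPS))
    if dropped:
        logger.warning("dropping out-of-range age group(s) %s", dropped)
        df = df[df["age_group"].isin(MODEL_AGE_GROUPS)]

    records = []
    for (country, sex, year), sub in df.groupby(["country", "sex", "year"]):
        groups = dict(zip(sub["age_group"], sub["count"]))
        counts = interpolate_age_groups(groups)
        records.append(
            pd.DataFrame(
                {
                    "country": country,
                    "field": field,
                    "sex": sex,
                    "age": AGES,
                    "year": int(year),
                    "count": counts,
                }
            )
        )
    if not records:
        raise ValueError("no modelled age groups present")
    panel = pd.concat(records, ignore_index=True)
    return panel.sort_values(
        ["country", "field", "sex", "year", "age"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# net rates and exit rates
# ---------------------------------------------------------------------------

def compute_net_rates(panel: pd.DataFrame, field: str) -> pd.DataFrame:
    """Cohort net rates of change for one field of a single-year panel.

    ``alpha(s, a, t) = (X(s, a+1, t+1) - X(s, a, t)) / X(s, a, t)``,
    flagged invalid (not raised) where the denominator stock is zero.

    Returns a frame with columns ``sex, age, year, alpha, valid``.
    """
    sub = panel[panel["field"] == field]
    if sub.empty:
        raise ValueError(f"field {field!r} not present in panel")
    wide = sub.pivot_table(
        index=["sex", "age"], columns="year", values="count", aggfunc="sum"
    )
    years = sorted(wide.columns)
    records = []
    for t in years:
        if t + 1 not in wide.columns:
            continue
        for sex in sorted(sub["sex"].unique()):
            for a in EXIT_AGES:
                if (sex, a) not in wide.index or (sex, a + 1) not in wide.index:
                    continue
                x0 = wide.loc[(sex, a), t]
                x1 = wide.loc[(sex, a + 1), t + 1]
                if np.isnan(x0) or np.isnan(x1):
                    continue
                valid = x0 > 0
                alpha = (x1 - x0) / x0 if valid else np.nan
                records.append(
                    {"sex": sex, "age": int(a), "year": int(t),
                     "alpha": alpha, "valid": bool(valid)}
                )
    if not records:
        raise ValueError("panel must cover at least two consecutive years")
    return pd.DataFrame.from_records(records)


def estimate_exit_rates(
    net: pd.DataFrame, reference: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Average the exit component of net rates into per-(sex, age) rates.

    ``gamma(s, a)`` is the unweighted mean over valid years of
    ``max(0, -alpha(s, a, t))``, clipped to [0, 1].  Cells with no valid
    year fall back to ``reference`` rates when provided.

    Returns a frame with columns ``sex, age, gamma, n_years_averaged,
    source`` where source is ``country`` or ``reference``.
    """
    if net is None or len(net) == 0:
        raise ValueError("empty net-rate table")
    ref_lookup: dict[tuple[str, int], float] = {}
    if reference is not None:
        ref_lookup = {
            (r.sex, int(r.age)): float(r.gamma) for r in reference.itertuples()
        }

    pairs = sorted({(r.sex, int(r.age)) for r in net.itertuples()})
    records = []
    for sex, a in pairs:
        cell = net[(net["sex"] == sex) & (net["age"] == a) & net["valid"]]
        if len(cell):
            exits = np.maximum(0.0, -cell["alpha"].to_numpy())
            gamma = float(np.clip(exits.mean(), 0.0, 1.0))
            records.append(
                {"sex": sex, "age": int(a), "gamma": gamma,
                 "n_years_averaged": int(len(cell)), "source": "country"}
            )
        elif (sex, a) in ref_lookup:
            records.append(
                {"sex": sex, "age": int(a), "gamma": ref_lookup[(sex, a)],
                 "n_years_averaged": 0, "source": "reference"}
            )
        else:
            raise ValueError(
                f"no valid observation for (sex={sex}, age={a}) "
                "and no reference rates supplied"
            )
    return pd.DataFrame.from_records(records)


def reference_exit_rates(panels: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Exit rates from stocks pooled (summed) across complete countries.

    Each input panel must be a complete single-year panel (as returned
    by :func:`interpolate_panel`).  Stocks are summed cell-wise over
    countries, then the usual net-rate / exit-rate estimation is applied.
    The result is marked ``source="reference"``.
    """
    panels = list(panels)
    if not panels:
        raise ValueError("no complete country panels supplied")
    pooled = pd.concat(panels, ignore_index=True)
    pooled = (
        pooled.groupby(["sex", "age", "year"], as_index=False)["count"].sum()
    )
    pooled["field"] = "all"
    pooled["country"] = "POOL"
    net = compute_net_rates(pooled, "all")
    rates = estimate_exit_rates(net)
    rates["source"] = "reference"
    return rates


def reference_age_distribution(
    panels: Iterable[pd.DataFrame], year: int
) -> pd.DataFrame:
    """Pooled age/sex distribution (fractions summing to 1) at ``year``.

    Used to initialise countries that report no age/sex-specific stocks.
    """
    pooled = pd.concat(list(panels), ignore_index=True)
    sl = pooled[pooled["year"] == year]
    if sl.empty:
        raise ValueError(f"year {year} absent from pooled panels")
    dist = sl.groupby(["sex", "age"], as_index=False)["count"].sum()
    total = dist["count"].sum()
    if total <= 0:
        raise ValueError("pooled stocks are zero")
    dist["share"] = dist["count"] / total
    return dist[["sex", "age", "share"]]


# ---------------------------------------------------------------------------
# inflow
# ---------------------------------------------------------------------------

@dataclass
class InflowSeries:
    """Observed annual entrants and the level assumed for the forecast.

    ``total(t) = graduates(t) + migrants(t)``; the annual total is
    distributed over entrants by ``sex_split`` and uniformly over the
    entry ages.
    """

    years: np.ndarray
    graduates: np.ndarray
    migrants: np.ndarray
    forecast_level: float = 0.0
    sex_split: tuple[float, float] = (0.5, 0.5)  # (F, M)
    entry_age_range: tuple[int, int] = ENTRY_AGE_RANGE

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.graduates = np.asarray(self.graduates, dtype=float)
        self.migrants = np.asarray(self.migrants, dtype=float)
        if not (len(self.years) == len(self.graduates) == len(self.migrants)):
            raise ValueError("years/graduates/migrants length mismatch")
        if abs(sum(self.sex_split) - 1.0) > 1e-12:
            raise ValueError("sex_split must sum to 1")
        self._lookup = {
            int(y): float(g + m)
            for y, g, m in zip(self.years, self.graduates, self.migrants)
        }

    @property
    def total(self) -> np.ndarray:
        return self.graduates + self.migrants

    def y(self, year: int) -> float:
        """Annual inflow: observed when available, else the forecast level."""
        return self._lookup.get(int(year), self.forecast_level)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "graduates": self.graduates,
                "migrants": self.migrants,
                "total": self.total,
            }
        )


def build_inflow(
    graduates: RawTable,
    migrants: RawTable | None,
    sex_split: tuple[float, float] = (0.5, 0.5),
) -> InflowSeries:
    """Combine graduate and migrant tables into one additive inflow series.

    Years present in only one table contribute zero from the other.
    """
    g = graduates.df.groupby("year")["count"].sum()
    m = (
        migrants.df.groupby("year")["count"].sum()
        if migrants is not None
        else pd.Series(dtype=float)
    )
    years = sorted(set(g.index) | set(m.index))
    return InflowSeries(
        years=np.array(years, dtype=int),
        graduates=np.array([g.get(y, 0.0) for y in years]),
        migrants=np.array([m.get(y, 0.0) for y in years]),
        sex_split=sex_split,
    )


def estimate_inflow(inflow: InflowSeries, window: tuple[int, int]) -> float:
    """Unweighted mean of annual inflow over ``window`` (inclusive).

    The returned level is held constant over all forecast years.
    """
    lo, hi = window
    mask = (inflow.years >= lo) & (inflow.years <= hi)
    if not mask.any():
        raise ValueError(f"inflow window {window} contains no observed years")
    return float(inflow.total[mask].mean())


def entrant_sex_split(panel: pd.DataFrame, year: int) -> tuple[float, float]:
    """(F, M) shares of the stock aged 25-34 in the reference year."""
    lo, hi = ENTRY_AGE_RANGE
    sl = panel[(panel["year"] == year) & panel["age"].between(lo, hi)]
    if sl.empty:
        raise ValueError(f"reference year {year} with ages {lo}-{hi} absent")
    by_sex = sl.groupby("sex")["count"].sum()
    f = float(by_sex.get("F", 0.0))
    m = float(by_sex.get("M", 0.0))
    total = f + m
    if total <= 0:
        raise ValueError(f"zero stock in entry ages at {year}")
    return (f / total, m / total)
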