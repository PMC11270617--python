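"""Tidy CSV input/output for the five table kinds the model consumes.

The on-disk dialect is deliberately simple: comma-separated UTF-8, one
observation per row, explicit header.  Column sets per table kind:

========================  ==============================================
table kind                columns
========================  ==============================================
stocks_by_age_sex         country, year, sex, age_group, count
stocks_by_field           country, year, field, count
graduates                 country, year, count
migrants                  country, year, count
population_projection     country, scenario, year, count
========================  ==============================================

Sex is binary ``{F, M}``; rows carrying totals (e.g. ``T``) are rejected
rather than summed, to avoid double counting.  Missing (country, year)
cells are represented by absent rows, never by zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import pandas as pd

#: Closed, ordered set of age-group labels accepted on input.
AGE_GROUPS: tuple[str, ...] = (
    "<25", "25-34", "35-44", "45-54", "55-64", "65-74", "75+",
)

#: Age groups inside the modelled 25-74 range; the open-ended groups
#: "<25" and "75+" are dropped (with a warning) before interpolation.
MODEL_AGE_GROUPS: tuple[str, ...] = ("25-34", "35-44", "45-54", "55-64", "65-74")

SEXES: tuple[str, str] = ("F", "M")

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "stocks_by_age_sex": ("country", "year", "sex", "age_group", "count"),
    "stocks_by_field": ("country", "year", "field", "count"),
    "graduates": ("country", "year", "count"),
    "migrants": ("country", "year", "count"),
    "population_projection": ("country", "scenario", "year", "count"),
}

#: Columns that together form the unique key of a row, per table kind.
TABLE_KEYS: dict[str, tuple[str, ...]] = {
    kind: tuple(c for c in cols if c != "count")
    for kind, cols in TABLE_SCHEMAS.items()
}


class SchemaError(ValueError):
    """The file header does not match the schema for the table kind."""


class ValidationError(ValueError):
    """The file parses but violates a content invariant."""


class InsufficientDataError(ValueError):
    """No usable calibration start year exists."""


@dataclass(frozen=True)
class RawTable:
    """A validated tidy table of one of the five supported kinds."""

    kind: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in TABLE_SCHEMAS:
            raise SchemaError(f"unknown table kind {self.kind!r}")

    @property
    def rows(self) -> pd.DataFrame:
        return self.df

    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())


def _validate_frame(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    if kind not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    schema = TABLE_SCHEMAS[kind]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{kind}: missing required column(s) {missing}; expected {list(schema)}"
        )
    extra = [c for c in df.columns if c not in schema]
    if extra:
        raise SchemaError(f"{kind}: unexpected column(s) {extra}")
    df = df.loc[:, list(schema)].copy()

    try:
        df["year"] = df["year"].astype(int)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{kind}: non-integer year values") from exc
    df["count"] = pd.to_numeric(df["count"], errors="coerce")

    bad = df.index[df["count"].isna()].tolist()
    if bad:
        raise ValidationError(f"{kind}: non-numeric count at rows {bad}")

    keys = list(TABLE_KEYS[kind])
    neg = df[df["count"] < 0]
    if len(neg):
        offenders = neg[keys].to_dict("records")
        raise ValidationError(f"{kind}: negative counts for keys {offenders}")

    dup = df[df.duplicated(subset=keys, keep=False)]
    if len(dup):
        offenders = dup[keys].drop_duplicates().to_dict("records")
        raise ValidationError(f"{kind}: duplicate keys {offenders}")

    if "sex" in schema:
        bad_sex = sorted(set(df["sex"]) - set(SEXES))
        if bad_sex:
            raise ValidationError(
                f"{kind}: sex must be one of {SEXES}, got {bad_sex} "
                "(totals rows are rejected, not summed)"
            )
    if "age_group" in schema:
        bad_grp = sorted(set(df["age_group"]) - set(AGE_GROUPS))
        if bad_grp:
            raise ValidationError(
                f"{kind}: unknown age_group label(s) {bad_grp}; "
                f"allowed: {list(AGE_GROUPS)}"
            )

    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)


def make_table(df: pd.DataFrame, kind: str) -> RawTable:
    """Validate an in-memory frame and wrap it as a :class:`RawTable`."""
    return RawTable(kind=kind, df=_validate_frame(df, kind))


def read_table(path: str | Path, table_kind: str) -> RawTable:
    """Read and validate a tidy CSV of the given kind.

    Raises :class:`SchemaError` for header problems and
    :class:`ValidationError` for content problems; a partially valid
    table is never returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return make_table(df, table_kind)


def write_table(table: RawTable, path: str | Path) -> None:
    """Write a table in the same dialect :func:`read_table` accepts."""
    keys = list(TABLE_KEYS[table.kind])
    out = table.df.sort_values(keys, kind="mergesort")
    out.to_csv(path, index=False)


@dataclass
class CountryConfig:
    """Per-country run configuration.

    ``t0`` may be left ``None`` to have the calibration start year
    selected automatically from data coverage and flagged breaks.
    """

    country: str
    last_data_year: int = 2019
    forecast_end: int = 2040
    t0: int | None = None
    fields: tuple[str, ...] = ("GP", "specialist")
    inflow_window: tuple[int, int] = (2014, 2019)
    breaks: tuple[int, ...] = ()
    inflow_mode: str = "window"  # "window" or "last3"

    def __post_init__(self) -> None:
        self.fields = tuple(self.fields)
        self.breaks = tuple(sorted(self.breaks))
        self.inflow_window = tuple(self.inflow_window)  # type: ignore[assignment]
        if not self.last_data_year < self.forecast_end:
            raise ValueError("last_data_year must precede forecast_end")
        if self.t0 is not None:
            if not self.t0 <= self.last_data_year:
                raise ValueError("t0 must not exceed last_data_year")
            late = [b for b in self.breaks if b >= self.t0]
            if late:
                raise ValueError(f"breaks {late} fall at or after t0={self.t0}")
        if self.inflow_mode not in ("window", "last3"):
            raise ValueError("inflow_mode must be 'window' or 'last3'")
        if len(self.fields) < 2:
            raise ValueError("at least two fields are required")


def _years_with_full_coverage(table: RawTable) -> list[int]:
    """Years in which every modelled age group is reported for both sexes."""
    if table.kind != "stocks_by_age_sex":
        return table.years()
    need = {(s, g) for s in SEXES for g in MODEL_AGE_GROUPS}
    ok = []
    for year, sub in table.df.groupby("year"):
        have = set(zip(sub["sex"], sub["age_group"]))
        if need <= have:
            ok.append(int(year))
    return sorted(ok)


def select_calibration_start(table: RawTable, config: CountryConfig) -> int:
    """Earliest break-free year with complete age/sex coverage.

    A break flagged in year ``b`` invalidates every year up to and
    including ``b``; the first usable year is therefore ``b + 1``.
    """
    covered = _years_with_full_coverage(table)
    if len(covered) < 2:
        raise InsufficientDataError(
            f"{config.country}: need at least two covered years, found {covered}"
        )
    floor = max(config.breaks) + 1 if config.breaks else min(covered)
    candidates = [y for y in covered if y >= floor and y <= config.last_data_year]
    if not candidates:
        raise InsufficientDataError(
            f"{config.country}: no break-free year with full coverage "
            f"(breaks={config.breaks}, covered={covered})"
        )
    return candidates[0]
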