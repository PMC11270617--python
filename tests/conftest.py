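import numpy as np
import pandas as pd
import pytest

from physflow.demography import AGES, InflowSeries
from physflow.eurostat_io import SEXES, CountryConfig, make_table
from physflow.synthetic_data import SyntheticSpec, generate_panel


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def synth(default_spec):
    """Noise-free 2-field synthetic country panel with ground truth."""
    return generate_panel(default_spec)


@pytest.fixture(scope="session")
def synth_config(default_spec):
    return default_spec.country_config()


@pytest.fixture
def stocks_table():
    """A minimal valid 3-row stocks_by_age_sex table."""
    df = pd.DataFrame(
        {
            "country": ["AT", "AT", "AT"],
            "year": [2000, 2000, 2000],
            "sex": ["F", "F", "M"],
            "age_group": ["25-34", "35-44", "25-34"],
            "count": [100.0, 120.0, 90.0],
        }
    )
    return make_table(df, "stocks_by_age_sex")


def panel_from_counts(
    counts_by_field: dict[str, float | np.ndarray],
    years,
    country: str = "XX",
) -> pd.DataFrame:
    """Tidy single-year panel with uniform (or given per-age) counts."""
    recs = []
    for field, val in counts_by_field.items():
        per_age = np.broadcast_to(np.asarray(val, dtype=float), AGES.shape)
        for year in years:
            for sex in SEXES:
                for a, c in zip(AGES, per_age):
                    recs.append(
                        {"country": country, "field": field, "sex": sex,
                         "age": int(a), "year": int(year), "count": float(c)}
                    )
    return pd.DataFrame.from_records(recs)


def flat_gamma(value: float = 0.0) -> pd.DataFrame:
    recs = [
        {"sex": s, "age": int(a), "gamma": value}
        for s in SEXES
        for a in AGES[:-1]
    ]
    return pd.DataFrame.from_records(recs)


def make_inflow(years, totals, forecast_level=0.0, sex_split=(0.5, 0.5)):
    totals = np.asarray(totals, dtype=float)
    return InflowSeries(
        years=np.asarray(years, dtype=int),
        graduates=totals,
        migrants=np.zeros_like(totals),
        forecast_level=forecast_level,
        sex_split=sex_split,
    )
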