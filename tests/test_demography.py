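import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from physflow import demography
from physflow.demography import (
    AGES,
    EXIT_AGES,
    InflowSeries,
    compute_net_rates,
    entrant_sex_split,
    estimate_exit_rates,
    estimate_inflow,
    interpolate_age_groups,
    reference_exit_rates,
)
from physflow.eurostat_io import MODEL_AGE_GROUPS

from conftest import panel_from_counts


def _oracle_interpolation(totals: dict[str, float]) -> np.ndarray:
    """Independent re-derivation: linear between group mid-ages, flat at
    the ends, clipped, rescaled per group."""
    bounds = {"25-34": (25, 34), "35-44": (35, 44), "45-54": (45, 54),
              "55-64": (55, 64), "65-74": (65, 74)}
    mids = [(lo + hi) / 2 for lo, hi in bounds.values()]
    means = [totals[g] / 10 for g in bounds]
    raw = []
    for a in range(25, 75):
        if a <= mids[0]:
            v = means[0]
        elif a >= mids[-1]:
            v = means[-1]
        else:
            for j in range(len(mids) - 1):
                if mids[j] <= a <= mids[j + 1]:
                    frac = (a - mids[j]) / (mids[j + 1] - mids[j])
                    v = means[j] + frac * (means[j + 1] - means[j])
                    break
        raw.append(max(v, 0.0))
    out = []
    for g, (lo, hi) in bounds.items():
        block = raw[lo - 25: hi - 25 + 1]
        s = sum(block)
        scale = totals[g] / s if s > 0 else 0.0
        out.extend(b * scale for b in block)
    return np.array(out)


class TestInterpolation:
    def test_uniform_groups(self):
        counts = interpolate_age_groups({g: 100.0 for g in MODEL_AGE_GROUPS})
        assert np.allclose(counts, 10.0)

    def test_two_level_profile_matches_oracle(self):
        totals = {"25-34": 100.0, "35-44": 200.0, "45-54": 200.0,
                  "55-64": 200.0, "65-74": 200.0}
        counts = interpolate_age_groups(totals)
        expected = _oracle_interpolation(totals)
        np.testing.assert_allclose(counts, expected, rtol=1e-12)
        # group sums conserved exactly, profile nondecreasing over 25-44
        assert counts[:10].sum() == pytest.approx(100.0, rel=1e-12)
        assert counts[10:20].sum() == pytest.approx(200.0, rel=1e-12)
        assert (np.diff(counts[:20]) >= -1e-12).all()

    def test_all_zero(self):
        counts = interpolate_age_groups({g: 0.0 for g in MODEL_AGE_GROUPS})
        assert (counts == 0).all()

    def test_missing_group_named(self):
        totals = {g: 1.0 for g in MODEL_AGE_GROUPS if g != "45-54"}
        with pytest.raises(ValueError, match="45-54"):
            interpolate_age_groups(totals)

    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e7, allow_nan=False),
            min_size=5, max_size=5,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_conserves_group_totals(self, vals):
        totals = dict(zip(MODEL_AGE_GROUPS, vals))
        counts = interpolate_age_groups(totals)
        assert (counts >= 0).all()
        for i, g in enumerate(MODEL_AGE_GROUPS):
            got = counts[10 * i: 10 * (i + 1)].sum()
            assert got == pytest.approx(totals[g], rel=1e-9, abs=1e-9)

    def test_matches_oracle_on_random_profiles(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            totals = dict(zip(MODEL_AGE_GROUPS, rng.uniform(0, 1e4, 5)))
            np.testing.assert_allclose(
                interpolate_age_groups(totals),
                _oracle_interpolation(totals),
                rtol=1e-10,
            )


def _two_year_panel(x0: float, x1: float, age: int = 40) -> pd.DataFrame:
    """Panel holding X(F, age, 2000) = x0 and X(F, age+1, 2001) = x1."""
    panel = panel_from_counts({"all": 50.0}, years=[2000, 2001])
    panel.loc[
        (panel.sex == "F") & (panel.age == age) & (panel.year == 2000), "count"
    ] = x0
    panel.loc[
        (panel.sex == "F") & (panel.age == age + 1) & (panel.year == 2001), "count"
    ] = x1
    return panel


class TestNetRates:
    def _alpha(self, net, sex, age, year):
        row = net[(net.sex == sex) & (net.age == age) & (net.year == year)]
        return row.iloc[0]

    def test_steady_state_zero(self):
        net = compute_net_rates(_two_year_panel(100.0, 100.0), "all")
        assert self._alpha(net, "F", 40, 2000)["alpha"] == 0.0

    def test_ten_percent_decline(self):
        net = compute_net_rates(_two_year_panel(100.0, 90.0), "all")
        assert self._alpha(net, "F", 40, 2000)["alpha"] == pytest.approx(-0.10)

    def test_zero_denominator_flagged_invalid(self):
        net = compute_net_rates(_two_year_panel(0.0, 10.0), "all")
        row = self._alpha(net, "F", 40, 2000)
        assert not row["valid"]

    def test_missing_field_raises(self):
        with pytest.raises(ValueError, match="nope"):
            compute_net_rates(_two_year_panel(1.0, 1.0), "nope")

    def test_single_year_panel_raises(self):
        panel = panel_from_counts({"all": 10.0}, years=[2000])
        with pytest.raises(ValueError):
            compute_net_rates(panel, "all")


def _net(alphas, sex="F", age=30):
    return pd.DataFrame(
        [
            {"sex": sex, "age": age, "year": 2000 + i, "alpha": a,
             "valid": not np.isnan(a)}
            for i, a in enumerate(alphas)
        ]
    )


class TestExitRates:
    def test_constant_alpha(self):
        rates = estimate_exit_rates(_net([-0.05] * 5))
        assert rates["gamma"].iloc[0] == pytest.approx(0.05)
        assert rates["n_years_averaged"].iloc[0] == 5

    def test_mixed_signs_use_max_zero_rule(self):
        rates = estimate_exit_rates(_net([0.02, -0.10]))
        assert rates["gamma"].iloc[0] == pytest.approx(0.05)

    def test_pure_growth_gives_zero(self):
        rates = estimate_exit_rates(_net([0.3, 0.3]))
        assert rates["gamma"].iloc[0] == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            estimate_exit_rates(pd.DataFrame())

    def test_fallback_to_reference(self):
        net = _net([np.nan, np.nan])
        ref = pd.DataFrame([{"sex": "F", "age": 30, "gamma": 0.07}])
        rates = estimate_exit_rates(net, reference=ref)
        assert rates["gamma"].iloc[0] == pytest.approx(0.07)
        assert rates["source"].iloc[0] == "reference"

    def test_no_valid_and_no_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            estimate_exit_rates(_net([np.nan]))

    def test_scale_invariance(self, synth):
        panel = synth.truth_panel.assign(field="all")
        panel = panel.groupby(
            ["country", "field", "sex", "age", "year"], as_index=False
        )["count"].sum()
        r1 = estimate_exit_rates(compute_net_rates(panel, "all"))
        scaled = panel.assign(count=panel["count"] * 7.3)
        r2 = estimate_exit_rates(compute_net_rates(scaled, "all"))
        np.testing.assert_allclose(r1["gamma"], r2["gamma"], rtol=1e-9, atol=1e-14)

    def test_gamma_bounded(self, synth):
        panel = synth.truth_panel.assign(field="all")
        rates = estimate_exit_rates(compute_net_rates(panel, "all"))
        assert rates["gamma"].between(0, 1).all()


class TestReferenceRates:
    def test_single_country_identity(self):
        panel = _two_year_panel(100.0, 90.0)
        own = estimate_exit_rates(compute_net_rates(panel, "all"))
        ref = reference_exit_rates([panel])
        np.testing.assert_allclose(own["gamma"], ref["gamma"], rtol=1e-12)
        assert (ref["source"] == "reference").all()

    def test_two_identical_countries(self):
        panel = _two_year_panel(100.0, 90.0)
        other = panel.assign(country="YY")
        ref1 = reference_exit_rates([panel])
        ref2 = reference_exit_rates([panel, other])
        np.testing.assert_allclose(ref1["gamma"], ref2["gamma"], rtol=1e-12)

    def test_pooled_rate_is_stock_weighted(self):
        # equal stocks with exit rates 0.02 and 0.06 pool to 0.04
        a = _two_year_panel(100.0, 98.0)
        b = _two_year_panel(100.0, 94.0).assign(country="YY")
        pooled = reference_exit_rates([a, b])
        row = pooled[(pooled.sex == "F") & (pooled.age == 40)]
        assert row["gamma"].iloc[0] == pytest.approx(0.04)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            reference_exit_rates([])


class TestInflow:
    def test_mean_over_window(self):
        s = InflowSeries(
            years=[2014, 2015, 2016],
            graduates=[100.0, 110.0, 120.0],
            migrants=[0.0, 0.0, 0.0],
        )
        assert estimate_inflow(s, (2014, 2016)) == pytest.approx(110.0)

    def test_single_year_window(self):
        s = InflowSeries(years=[2019], graduates=[200.0], migrants=[0.0])
        assert estimate_inflow(s, (2019, 2019)) == 200.0

    def test_constant_series(self):
        s = InflowSeries(
            years=range(2014, 2020),
            graduates=[400.0] * 6,
            migrants=[100.0] * 6,
        )
        assert estimate_inflow(s, (2014, 2019)) == pytest.approx(500.0)

    def test_empty_window_raises(self):
        s = InflowSeries(years=[2014], graduates=[1.0], migrants=[0.0])
        with pytest.raises(ValueError):
            estimate_inflow(s, (2000, 2001))

    def test_total_is_additive(self):
        s = InflowSeries(years=[2014], graduates=[10.0], migrants=[5.0])
        assert s.y(2014) == 15.0

    def test_sex_split_must_normalize(self):
        with pytest.raises(ValueError):
            InflowSeries(
                years=[2014], graduates=[1.0], migrants=[0.0],
                sex_split=(0.6, 0.6),
            )


class TestEntrantSexSplit:
    def _panel(self, f, m):
        panel = panel_from_counts({"all": 0.0}, years=[2019])
        mask_age = panel["age"].between(25, 34)
        panel.loc[mask_age & (panel.sex == "F"), "count"] = f / 10
        panel.loc[mask_age & (panel.sex == "M"), "count"] = m / 10
        return panel

    def test_sixty_forty(self):
        assert entrant_sex_split(self._panel(60, 40), 2019) == pytest.approx((0.6, 0.4))

    def test_symmetric(self):
        assert entrant_sex_split(self._panel(50, 50), 2019) == pytest.approx((0.5, 0.5))

    def test_boundary(self):
        assert entrant_sex_split(self._panel(0, 100), 2019) == pytest.approx((0.0, 1.0))

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            entrant_sex_split(self._panel(0, 0), 2019)

    def test_missing_year_raises(self):
        with pytest.raises(ValueError):
            entrant_sex_split(self._panel(1, 1), 1990)
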