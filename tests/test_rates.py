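"""Stratum aggregation, direct standardization and inequality contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import premort as pm
from premort.rates import AGE_GROUP_LABELS, StandardPopulation

from .conftest import ONE_PERIOD


def _uniform_age_rates(rate_per_100k: float, py_per_group: float = 50_000.0):
    return pd.DataFrame(
        {
            "age_group": AGE_GROUP_LABELS,
            "deaths": [rate_per_100k / 1e5 * py_per_group] * len(AGE_GROUP_LABELS),
            "person_years": [py_per_group] * len(AGE_GROUP_LABELS),
        }
    )


class TestAggregate:
    def test_person_years_sum_over_period(self):
        pops = pd.DataFrame(
            {
                "period": ["1998-2003"] * 6,
                "sex": ["M"] * 6,
                "decile": [1] * 6,
                "age": [62] * 6,
                "year": range(1998, 2004),
                "count": [1000] * 6,
            }
        )
        deaths = pd.DataFrame(
            {"period": ["1998-2003"], "sex": ["M"], "decile": [1], "age": [62]}
        )
        strata = pm.aggregate_strata(deaths, pops)
        row = strata[(strata["age_group"] == "60-64")].iloc[0]
        assert row["person_years"] == 6000
        assert row["deaths"] == 1

    def test_empty_cell_retained_with_zero_deaths(self):
        pops = pd.DataFrame(
            {"period": ["p"] * 2, "sex": ["M", "F"], "decile": [1, 1],
             "age": [30, 30], "year": [1998] * 2, "count": [500, 600]}
        )
        deaths = pd.DataFrame({"period": ["p"], "sex": ["M"], "decile": [1], "age": [30]})
        strata = pm.aggregate_strata(deaths, pops)
        f_row = strata[(strata["sex"] == "F") & (strata["age_group"] == "30-34")]
        assert len(f_row) == 1 and f_row.iloc[0]["deaths"] == 0

    def test_ages_outside_1_74_rejected_and_counted(self):
        pops = pd.DataFrame(
            {"period": ["p"], "sex": ["M"], "decile": [1], "age": [40],
             "year": [1998], "count": [100]}
        )
        deaths = pd.DataFrame(
            {"period": ["p"] * 3, "sex": ["M"] * 3, "decile": [1] * 3, "age": [0, 40, 80]}
        )
        strata = pm.aggregate_strata(deaths, pops)
        assert strata.attrs["n_rejected_age"] == 2
        assert strata["deaths"].sum() == 1

    def test_totals_match_groupby_oracle(self, small_tagged):
        strata = pm.aggregate_strata(small_tagged.deaths, small_tagged.populations)
        allc = strata[strata["cause"] == "ALL"]
        assert allc["deaths"].sum() == len(small_tagged.deaths)
        oracle = (
            small_tagged.deaths.groupby(["sex", "decile"], observed=True)
            .size()
            .sort_index()
        )
        got = allc.groupby(["sex", "decile"], observed=True)["deaths"].sum().sort_index()
        pd.testing.assert_series_equal(
            got, oracle, check_names=False, check_dtype=False
        )


class TestStandardize:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.1, max_value=1e6),
            min_size=len(AGE_GROUP_LABELS),
            max_size=len(AGE_GROUP_LABELS),
        )
    )
    def test_constant_rate_identity_any_weights(self, weights):
        std = StandardPopulation(weights=tuple(weights))
        r = pm.standardize(_uniform_age_rates(100.0), std)
        assert math.isclose(r.rate, 100.0, rel_tol=1e-12)

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        df = _uniform_age_rates(100.0)
        df["deaths"] = rng.integers(0, 200, len(df))
        base = StandardPopulation(tuple(rng.uniform(100, 9000, len(df))))
        scaled = StandardPopulation(tuple(np.array(base.weights) * 7.5))
        assert math.isclose(
            pm.standardize(df, base).rate, pm.standardize(df, scaled).rate, rel_tol=1e-12
        )

    def test_zero_deaths_zero_rate_and_variance(self):
        df = _uniform_age_rates(0.0)
        r = pm.standardize(df)
        assert r.rate == 0 and r.variance == 0 and r.lo == 0 and r.hi == 0

    def test_three_group_hand_weighted_mean(self):
        std = StandardPopulation(
            weights=(1000, 2000, 1000), labels=("a", "b", "c")
        )
        df = pd.DataFrame(
            {
                "age_group": ["a", "b", "c"],
                "deaths": [50, 200, 200],          # rates 50, 100, 200 per 100k
                "person_years": [100_000, 200_000, 100_000],
            }
        )
        r = pm.standardize(df, std)
        assert math.isclose(r.rate, 112.5, rel_tol=1e-12)

    def test_zero_person_years_with_deaths_errors(self):
        df = _uniform_age_rates(100.0)
        df.loc[0, "person_years"] = 0
        with pytest.raises(ValueError, match="zero person-years"):
            pm.standardize(df)

    def test_empty_group_warns_but_included(self):
        df = _uniform_age_rates(100.0)
        df.loc[0, ["deaths", "person_years"]] = 0
        with pytest.warns(UserWarning, match="no person-years"):
            r = pm.standardize(df)
        assert r.rate < 100.0  # that group's weight pulls the mean down


class TestContrast:
    def test_identity_is_exact_null(self):
        r = pm.StandardizedRate(rate=200.0, variance=16.0, lo=192.2, hi=207.8)
        c = pm.contrast(r, r)
        assert c.absolute == 0 and c.relative_pct == 0 and c.ratio == 1
        assert c.z == 0 and c.p == 1

    def test_antisymmetry_of_absolute_difference(self):
        r1 = pm.StandardizedRate(250.0, 25.0, 240.2, 259.8)
        r2 = pm.StandardizedRate(200.0, 16.0, 192.2, 207.8)
        assert pm.contrast(r1, r2).absolute == -pm.contrast(r2, r1).absolute

    def test_relative_consistent_with_absolute(self):
        r1 = pm.StandardizedRate(300.0, 25.0, 290.2, 309.8)
        r2 = pm.StandardizedRate(200.0, 16.0, 192.2, 207.8)
        c = pm.contrast(r1, r2)
        assert math.isclose(c.relative_pct, 100 * c.absolute / r2.rate)

    def test_zero_reference_flagged(self):
        r1 = pm.StandardizedRate(100.0, 4.0, 96.1, 103.9)
        r0 = pm.StandardizedRate(0.0, 0.0, 0.0, 0.0)
        c = pm.contrast(r1, r0)
        assert math.isnan(c.relative_pct) and math.isnan(c.ratio)

    def test_temporal_change_toy(self):
        first = pm.StandardizedRate(200.0, 4.0, 196.1, 203.9)
        last = pm.StandardizedRate(150.0, 4.0, 146.1, 153.9)
        ch = pm.temporal_change(first, last)
        assert ch.absolute == -50.0
        assert math.isclose(ch.relative_pct, -25.0)

    def test_gradient_recovery_on_synthetic(self, small_registry, small_tagged):
        """Estimated most/least ratio tracks the programmed gradient."""
        _, _, _, _, truth = small_registry
        strata = pm.aggregate_strata(small_tagged.deaths, small_tagged.populations)
        allc = strata[strata["cause"] == "ALL"]
        rates = {}
        for d in (1, 10):
            grp = (
                allc[allc["decile"] == d]
                .groupby("age_group", observed=True)[["deaths", "person_years"]]
                .sum()
                .reset_index()
            )
            rates[d] = pm.standardize(grp)
        c = pm.contrast(rates[1], rates[10])
        se_log = math.sqrt(
            rates[1].variance / rates[1].rate ** 2 + rates[10].variance / rates[10].rate ** 2
        )
        truth_ratio = truth.analytic_ratio("M") * 0.5 + truth.analytic_ratio("F") * 0.5
        assert abs(math.log(c.ratio) - math.log(truth_ratio)) < 3 * se_log
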