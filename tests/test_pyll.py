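"""Potential years of life lost: crude totals, the counterfactual
decomposition and age standardization."""

import math

import numpy as np
import pandas as pd
import pytest

import premort as pm
from premort.rates import AGE_GROUP_LABELS, StandardPopulation


def _deaths(ages, decile=1, sex="M", period="p"):
    return pd.DataFrame(
        {"age": ages, "sex": sex, "period": period, "decile": decile}
    )


class TestCrude:
    @pytest.mark.parametrize(
        "ages,expected",
        [([70], 5), ([60, 60, 74], 31), ([74], 1), ([1], 74)],
    )
    def test_years_to_75(self, ages, expected):
        assert pm.crude_pyll(_deaths(ages)) == expected

    def test_midyear_convention_optional(self):
        assert pm.crude_pyll(_deaths([70]), midyear=True) == 4.5

    @pytest.mark.parametrize("bad_age", [0, 75, 90])
    def test_age_bounds_enforced(self, bad_age):
        with pytest.raises(ValueError):
            pm.crude_pyll(_deaths([bad_age]))

    def test_grouped_totals(self):
        d = pd.concat([_deaths([70, 70], decile=1), _deaths([74], decile=10)])
        out = pm.crude_pyll(d, by=["decile"])
        assert out.loc[1] == 10 and out.loc[10] == 1


def _two_decile_toy():
    deaths = pd.concat(
        [_deaths([65] * 50, decile=1), _deaths([65] * 20, decile=10)]
    ).reset_index(drop=True)
    pops = pd.DataFrame(
        {
            "sex": "M", "period": "p",
            "decile": [1, 10], "age": [65, 65],
            "count": [10_000, 10_000], "year": [1998, 1998],
        }
    )
    return deaths, pops


class TestDecomposition:
    def test_two_decile_hand_computation(self):
        deaths, pops = _two_decile_toy()
        res = pm.pyll_inequality(deaths, pops, reference_decile=10)
        # expected deaths in decile 1 = 20; excess = 30 deaths * 10 years
        assert res.excess == pytest.approx(300)
        assert res.observed == pytest.approx(50 * 10 + 20 * 10)

    def test_null_gradient_zero_excess(self):
        deaths = pd.concat(
            [_deaths([65] * 20, decile=d) for d in range(1, 11)]
        ).reset_index(drop=True)
        pops = pd.DataFrame(
            {"sex": "M", "period": "p", "decile": range(1, 11), "age": 65,
             "count": 10_000, "year": 1998}
        )
        res = pm.pyll_inequality(deaths, pops, reference_decile=10)
        assert res.excess == pytest.approx(0, abs=1e-9)

    def test_identity_observed_equals_expected_plus_excess(self):
        deaths, pops = _two_decile_toy()
        table = pm.pyll_decomposition(deaths, pops, reference_decile=10)
        assert (
            (table["observed"] - table["expected"] - table["excess"]).abs().max() == 0
        )
        ref = table[table["decile"] == 10]
        assert ref["excess"].abs().max() == pytest.approx(0, abs=1e-9)

    def test_decompose_from_totals(self):
        res = pm.decompose(observed=1000.0, expected=700.0)
        assert res.excess == 300.0
        assert res.share_pct == pytest.approx(30.0)


class TestStandardizedPyll:
    def test_constant_rate_identity(self):
        # every age group: PYLL rate 5,000 per 100,000
        rows, pops = [], []
        for lab in AGE_GROUP_LABELS:
            lo = int(lab.split("-")[0])
            n_deaths = 100
            pyll_each = 75 - lo
            py = n_deaths * pyll_each / 5000 * 1e5
            rows.append(_deaths([lo] * n_deaths))
            pops.append(
                pd.DataFrame(
                    {"sex": ["M"], "period": ["p"], "decile": [1], "age": [lo],
                     "count": [py], "year": [1998]}
                )
            )
        deaths = pd.concat(rows).reset_index(drop=True)
        populations = pd.concat(pops).reset_index(drop=True)
        out = pm.standardized_pyll(deaths, populations, by=["sex"])
        assert out["aspyll"].iloc[0] == pytest.approx(5000, rel=1e-12)

    def test_weighted_mean_matches_hand_formula(self):
        # equal weights; PYLL rates 4000/100k in 7 groups, 6000 in the other 8
        std = StandardPopulation(weights=(1000,) * len(AGE_GROUP_LABELS))
        rows, pops = [], []
        for i, lab in enumerate(AGE_GROUP_LABELS):
            lo = int(lab.split("-")[0])
            rate = 4000 if i < 7 else 6000
            n_deaths = 100
            py = n_deaths * (75 - lo) / rate * 1e5
            rows.append(_deaths([lo] * n_deaths))
            pops.append(
                pd.DataFrame(
                    {"sex": ["M"], "period": ["p"], "decile": [1], "age": [lo],
                     "count": [py], "year": [1998]}
                )
            )
        deaths = pd.concat(rows).reset_index(drop=True)
        populations = pd.concat(pops).reset_index(drop=True)
        out = pm.standardized_pyll(deaths, populations, standard=std, by=["sex"])
        assert out["aspyll"].iloc[0] == pytest.approx((7 * 4000 + 8 * 6000) / 15, rel=1e-12)

    def test_zero_deaths_zero(self):
        deaths = _deaths([], decile=1).astype({"age": int})
        pops = pd.DataFrame(
            {"sex": ["M"], "period": ["p"], "decile": [1], "age": [30],
             "count": [1000], "year": [1998]}
        )
        out = pm.standardized_pyll(deaths, pops, by=["sex"])
        assert out["aspyll"].iloc[0] == 0


class TestRankContributions:
    def test_single_cause_is_everything(self):
        df = pd.DataFrame({"cause": ["C34"], "observed": [500.0]})
        out = pm.rank_contributions(df)
        assert out["pct_observed"].iloc[0] == pytest.approx(100.0)

    def test_arithmetic_and_order(self):
        df = pd.DataFrame(
            {"cause": ["a", "b"], "observed": [100.0, 300.0], "excess": [10.0, 30.0]}
        )
        out = pm.rank_contributions(df)
        assert out["cause"].tolist() == ["b", "a"]
        assert out["pct_observed"].tolist() == pytest.approx([75.0, 25.0])
        assert out["pct_excess"].tolist() == pytest.approx([75.0, 25.0])

    def test_all_cause_row_sets_denominator(self):
        df = pd.DataFrame(
            {"cause": ["ALL", "a", "b"], "observed": [1000.0, 300.0, 100.0]}
        )
        out = pm.rank_contributions(df)
        assert "ALL" not in out["cause"].values
        assert out["pct_observed"].tolist() == pytest.approx([30.0, 10.0])
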