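"""Potential years of life lost (PYLL) and its inequality decomposition.

A death at completed age x (1 <= x <= 74) loses 75 - x potential years.
Crude PYLL is the uncorrected sum over deaths — actual deaths, not deaths
of a theoretical standard population.  The PYLL attributable to
socioeconomic inequality is the counterfactual decomposition: expected
deaths per single-year age under the least-deprived decile's age-sex-period
rates, converted to expected PYLL, with the excess = observed - expected.
Age-standardized PYLL per 100,000 persons (ASPYLL) uses the same standard
and contrast conventions as the mortality rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rates import ESP2013_1_74, StandardPopulation, age_group_of

__all__ = [
    "PyllResult",
    "crude_pyll",
    "pyll_decomposition",
    "pyll_inequality",
    "standardized_pyll",
    "rank_contributions",
    "decompose",
]

UPPER_AGE = 75


@dataclass(frozen=True)
class PyllResult:
    """Observed / expected / excess years of life lost for one scope."""

    scope: str
    observed: float
    expected: float

    @property
    def excess(self) -> float:
        return self.observed - self.expected

    @property
    def share_pct(self) -> float:
        """Excess as % of observed PYLL (the share due to inequality)."""
        if self.observed == 0:
            return float("nan")
        return 100.0 * self.excess / self.observed


def decompose(observed: float, expected: float, scope: str = "all") -> PyllResult:
    """Observed/expected totals -> excess and share-of-observed."""
    return PyllResult(scope=scope, observed=observed, expected=expected)


def _years_lost(ages: pd.Series, midyear: bool = False) -> pd.Series:
    if not ages.between(1, UPPER_AGE - 1).all():
        bad = ages[~ages.between(1, UPPER_AGE - 1)].unique()
        raise ValueError(f"ages outside 1-{UPPER_AGE - 1}: {sorted(bad)[:10]}")
    yl = (UPPER_AGE - ages).astype(float)
    if midyear:
        yl = yl - 0.5
    return yl


def crude_pyll(deaths: pd.DataFrame, by: list[str] | None = None, midyear: bool = False):
    """Crude PYLL: sum over deaths of years remaining to the 75th birthday.

    Default convention is 75 - x for completed age x (integer-valued);
    ``midyear=True`` switches to 75 - (x + 0.5).  Returns a float for the
    whole table, or a Series grouped by ``by``.
    """
    yl = _years_lost(deaths["age"], midyear=midyear)
    if by is None:
        return float(yl.sum())
    return yl.groupby([deaths[k] for k in by], observed=True).sum().rename("pyll")


def pyll_decomposition(
    deaths: pd.DataFrame,
    populations: pd.DataFrame,
    reference_decile: int = 10,
    by: list[str] | None = None,
    midyear: bool = False,
) -> pd.DataFrame:
    """Per-decile observed vs counterfactual expected PYLL.

    Expected deaths at each single-year age in every decile apply the
    reference decile's age-sex-period rate to that decile's person-years;
    expected PYLL weights them by remaining years.  Returns one row per
    (by..., decile) with observed, expected and excess PYLL; the reference
    decile's excess is zero by construction.
    """
    if by is None:
        by = ["sex", "period"]
    keys_age = by + ["age"]

    d = deaths.copy()
    d["yl"] = _years_lost(d["age"], midyear=midyear)
    obs_age = (
        d.groupby(by + ["decile", "age"], observed=True)
        .agg(deaths=("yl", "size"), pyll=("yl", "sum"))
        .reset_index()
    )
    py = (
        populations.groupby(by + ["decile", "age"], observed=True)["count"]
        .sum()
        .rename("person_years")
        .reset_index()
    )
    ref_d = (
        obs_age[obs_age["decile"] == reference_decile]
        .groupby(keys_age, observed=True)["deaths"]
        .sum()
        .rename("ref_deaths")
    )
    ref_py = (
        py[py["decile"] == reference_decile]
        .groupby(keys_age, observed=True)["person_years"]
        .sum()
        .rename("ref_py")
    )
    ref = pd.concat([ref_py, ref_d], axis=1).fillna({"ref_deaths": 0.0}).reset_index()
    if (ref["ref_py"] <= 0).any():
        bad = ref.loc[ref["ref_py"] <= 0, keys_age].head(5)
        raise ValueError(f"reference decile has zero person-years:\n{bad.to_string(index=False)}")
    grid = py.merge(ref, on=keys_age, how="left")
    missing_ref = grid["ref_py"].isna()
    if missing_ref.any():
        # ages with exposure but no reference exposure at all: no deaths can
        # be expected there unless observed deaths exist, which is an error
        ages_obs = obs_age.merge(grid.loc[missing_ref, by + ["decile", "age"]], on=by + ["decile", "age"])
        if len(ages_obs):
            raise ValueError("observed deaths at ages with no reference-decile exposure")
        grid = grid[~missing_ref]
    grid["exp_deaths"] = grid["ref_deaths"] / grid["ref_py"] * grid["person_years"]
    weight = UPPER_AGE - grid["age"] - (0.5 if midyear else 0.0)
    grid["exp_pyll"] = grid["exp_deaths"] * weight

    out = (
        grid.groupby(by + ["decile"], observed=True)["exp_pyll"].sum().rename("expected").reset_index()
    )
    obs = (
        obs_age.groupby(by + ["decile"], observed=True)["pyll"].sum().rename("observed").reset_index()
    )
    out = out.merge(obs, on=by + ["decile"], how="left").fillna({"observed": 0.0})
    out["excess"] = out["observed"] - out["expected"]
    return out[by + ["decile", "observed", "expected", "excess"]]


def pyll_inequality(
    deaths: pd.DataFrame,
    populations: pd.DataFrame,
    reference_decile: int = 10,
    by: list[str] | None = None,
    midyear: bool = False,
) -> PyllResult:
    """Pooled (all-decile) PYLL decomposition for the supplied scope."""
    table = pyll_decomposition(deaths, populations, reference_decile, by=by, midyear=midyear)
    return PyllResult(
        scope="pooled",
        observed=float(table["observed"].sum()),
        expected=float(table["expected"].sum()),
    )


def standardized_pyll(
    deaths: pd.DataFrame,
    populations: pd.DataFrame,
    standard: StandardPopulation = ESP2013_1_74,
    by: list[str] | None = None,
    midyear: bool = False,
) -> pd.DataFrame:
    """Age-standardized PYLL per 100,000 persons, one row per scope.

    Per age group a: PYLL rate = PYLL_a / person_years_a * 100,000;
    ASPYLL = sum_a w_a * rate_a / sum_a w_a.  Age groups with exposure but
    no deaths contribute rate 0.
    """
    if by is None:
        by = ["sex", "period", "decile"]
    d = deaths.copy()
    d["yl"] = _years_lost(d["age"], midyear=midyear)
    d["age_group"] = age_group_of(d["age"])
    p = populations.copy()
    p["age_group"] = age_group_of(p["age"])

    pyll_a = d.groupby(by + ["age_group"], observed=False)["yl"].sum().rename("pyll")
    py_a = p.groupby(by + ["age_group"], observed=False)["count"].sum().rename("person_years")
    tab = pd.concat([pyll_a, py_a], axis=1).fillna(0.0).reset_index()
    if ((tab["person_years"] == 0) & (tab["pyll"] > 0)).any():
        raise ValueError("PYLL observed in an age group with zero person-years")

    w = standard.as_series()
    tab["weight"] = tab["age_group"].astype(str).map(w)
    rate = np.divide(
        tab["pyll"], tab["person_years"],
        out=np.zeros(len(tab)), where=tab["person_years"] > 0,
    )
    tab["wrate"] = tab["weight"] * rate * 1e5
    out = (
        tab.groupby(by, observed=True)["wrate"].sum().div(float(w.sum())).rename("aspyll").reset_index()
    )
    return out


def rank_contributions(pyll_by_cause: pd.DataFrame) -> pd.DataFrame:
    """Cause-level contributions to overall (and excess) PYLL, ranked.

    Input: one row per cause with columns cause, observed and optionally
    excess.  Percentages are taken against the all-cause ("ALL") row when
    present, else against the column sum; the ALL row is dropped from the
    ranking.
    """
    df = pyll_by_cause.copy()
    if (df["cause"] == "ALL").any():
        tot_obs = float(df.loc[df["cause"] == "ALL", "observed"].iloc[0])
        tot_exc = (
            float(df.loc[df["cause"] == "ALL", "excess"].iloc[0])
            if "excess" in df.columns
            else None
        )
        df = df[df["cause"] != "ALL"].copy()
    else:
        tot_obs = float(df["observed"].sum())
        tot_exc = float(df["excess"].sum()) if "excess" in df.columns else None
    df["pct_observed"] = 100.0 * df["observed"] / tot_obs if tot_obs else np.nan
    if tot_exc is not None and tot_exc != 0:
        df["pct_excess"] = 100.0 * df["excess"] / tot_exc
    return df.sort_values(
        ["pct_observed", "cause"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
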