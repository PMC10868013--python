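"""Direct age standardization of premature mortality and inequality contrasts.

Deaths and person-years are aggregated to analysis strata
(period x sex x deprivation decile x cause node x 5-year age group, with a
1-4 group for young children), and directly standardized to a fixed
standard population:

    ASMR = 100,000 * sum_a w_a * (d_a / n_a) / sum_a w_a

with the conventional Poisson variance for a directly standardized rate

    Var  = 100,000^2 * sum_a w_a^2 * d_a / n_a^2 / (sum_a w_a)^2

and a normal-approximation 95% interval floored at zero.  Inequality is
expressed through absolute differences, relative differences
(100 * (r1 - r2) / r2), rate ratios with log-normal intervals, and a z-test
on the difference of the two standardized rates.

The shipped default standard is the 2013 European Standard Population
restricted to ages 1-74 (the 1-4 weight is four fifths of the 0-4 weight);
any contiguous positive-weight standard covering 1-74 may be substituted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AGE_GROUPS",
    "AGE_GROUP_LABELS",
    "ESP2013_1_74",
    "StandardPopulation",
    "StandardizedRate",
    "RateContrast",
    "age_group_of",
    "aggregate_strata",
    "standardize",
    "contrast",
    "temporal_change",
]

_Z95 = 1.959963984540054

#: (lower, upper) inclusive bounds of the analysis age groups, ages 1-74.
AGE_GROUPS: list[tuple[int, int]] = [(1, 4)] + [(lo, lo + 4) for lo in range(5, 71, 5)]
AGE_GROUP_LABELS: list[str] = [f"{lo}-{hi}" for lo, hi in AGE_GROUPS]


@dataclass(frozen=True)
class StandardPopulation:
    """Ordered age-group weights (persons) for direct standardization."""

    weights: tuple[float, ...]
    labels: tuple[str, ...] = tuple(AGE_GROUP_LABELS)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.labels):
            raise ValueError("one weight per age group required")
        if any(w <= 0 for w in self.weights):
            raise ValueError("standard-population weights must be strictly positive")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.labels), name="weight")


#: European Standard Population 2013, ages 1-74 (1-4 = 4/5 of the 0-4 weight).
ESP2013_1_74 = StandardPopulation(
    weights=(
        4000, 5500, 5500, 5500, 6000, 6000, 6500, 7000,
        7000, 7000, 7000, 6500, 6000, 5500, 5000,
    )
)


def age_group_of(ages) -> pd.Categorical:
    """Map completed ages 1-74 to the analysis age-group labels."""
    bins = [g[0] for g in AGE_GROUPS] + [AGE_GROUPS[-1][1] + 1]
    return pd.cut(ages, bins=bins, labels=AGE_GROUP_LABELS, right=False, include_lowest=True)


def aggregate_strata(
    deaths: pd.DataFrame,
    populations: pd.DataFrame,
    hierarchy=None,
) -> pd.DataFrame:
    """Aggregate tagged records to analysis strata.

    ``deaths`` needs columns (age, sex, period, decile) and, when a
    hierarchy is given, ``icd10``; ``populations`` needs
    (age, sex, period, decile, count).  Person-years per stratum are the
    sum of mid-year population counts over the period's years; strata with
    zero deaths are retained with their person-years.  Deaths at ages
    outside 1-74 are rejected and counted in ``result.attrs``.

    Returns a tidy frame: period, sex, decile, cause, age_group, deaths,
    person_years — with cause "ALL" for all-cause and one block per
    hierarchy node when a hierarchy is supplied.
    """
    ok = deaths["age"].between(1, 74)
    n_rejected = int((~ok).sum())
    deaths = deaths.loc[ok].copy()
    if not populations["age"].between(1, 74).all():
        populations = populations.loc[populations["age"].between(1, 74)].copy()

    deaths["age_group"] = age_group_of(deaths["age"])
    pop = populations.copy()
    pop["age_group"] = age_group_of(pop["age"])

    keys = ["period", "sex", "decile", "age_group"]
    py = (
        pop.groupby(keys, observed=False)["count"].sum().rename("person_years").reset_index()
    )
    py = py[py["person_years"] > 0].reset_index(drop=True)

    def _block(dsub: pd.DataFrame, cause: str) -> pd.DataFrame:
        cnt = dsub.groupby(keys, observed=False).size().rename("deaths").reset_index()
        out = py.merge(cnt, on=keys, how="left")
        out["deaths"] = out["deaths"].fillna(0).astype(int)
        out["cause"] = cause
        return out

    blocks = [_block(deaths, "ALL")]
    if hierarchy is not None:
        ann = hierarchy.annotate(deaths["icd10"])
        for node in hierarchy.nodes:
            col = {1: "chapter", 2: "level2", 3: "level3"}[node.level]
            blocks.append(_block(deaths[ann[col] == node.node_id], node.node_id))
    out = pd.concat(blocks, ignore_index=True)
    out = out[["period", "sex", "decile", "cause", "age_group", "deaths", "person_years"]]
    out.attrs["n_rejected_age"] = n_rejected
    return out


@dataclass(frozen=True)
class StandardizedRate:
    """Directly standardized rate per 100,000 person-years."""

    rate: float
    variance: float
    lo: float
    hi: float
    deaths: int = 0

    @classmethod
    def from_interval(cls, rate: float, lo: float, hi: float, deaths: int = 0) -> "StandardizedRate":
        """Reconstruct a rate object from a printed point estimate and 95% CI.

        Useful for worked examples that start from published tables: the
        variance is back-derived from the interval half-width under the
        normal approximation.
        """
        var = ((hi - lo) / (2 * _Z95)) ** 2
        return cls(rate=rate, variance=var, lo=lo, hi=hi, deaths=deaths)


def standardize(
    age_rates: pd.DataFrame, standard: StandardPopulation = ESP2013_1_74
) -> StandardizedRate:
    """Directly standardize one scope's age-specific counts.

    ``age_rates`` must carry one row per age group with columns
    (age_group, deaths, person_years).  A group with zero person-years and
    zero deaths still contributes its standard weight at rate 0 (with a
    warning); zero person-years with deaths present is an error.
    """
    w = standard.as_series()
    df = age_rates.set_index("age_group").reindex(w.index)
    d = df["deaths"].fillna(0).to_numpy(dtype=float)
    n = df["person_years"].fillna(0).to_numpy(dtype=float)
    bad = (n == 0) & (d > 0)
    if bad.any():
        raise ValueError(
            f"zero person-years with deaths present in age group(s) "
            f"{list(w.index[bad])}"
        )
    empty = n == 0
    if empty.any() and not empty.all():
        warnings.warn(
            f"age group(s) {list(w.index[empty])} have no person-years; "
            "included at rate 0",
            stacklevel=2,
        )
    r = np.divide(d, n, out=np.zeros_like(d), where=n > 0)
    v = np.divide(d, n * n, out=np.zeros_like(d), where=n > 0)
    wsum = float(w.sum())
    wa = w.to_numpy(dtype=float)
    rate = 1e5 * float((wa * r).sum()) / wsum
    var = 1e10 * float((wa * wa * v).sum()) / wsum**2
    se = math.sqrt(var)
    return StandardizedRate(
        rate=rate,
        variance=var,
        lo=max(0.0, rate - _Z95 * se),
        hi=rate + _Z95 * se,
        deaths=int(d.sum()),
    )


@dataclass(frozen=True)
class RateContrast:
    """Absolute/relative difference, ratio with 95% interval, z-test."""

    absolute: float
    relative_pct: float
    ratio: float
    ratio_lo: float
    ratio_hi: float
    z: float
    p: float


def contrast(r1: StandardizedRate, r2: StandardizedRate) -> RateContrast:
    """Compare two standardized rates (r1 vs reference r2).

    Ratio interval from the log-normal approximation with
    se(log ratio) = sqrt(V1/r1^2 + V2/r2^2); two-sided p from a z-test on
    the rate difference.  A zero reference leaves the relative difference
    and ratio undefined (NaN).
    """
    absolute = r1.rate - r2.rate
    vsum = r1.variance + r2.variance
    if absolute == 0.0:
        z = 0.0
    elif vsum > 0:
        z = absolute / math.sqrt(vsum)
    else:
        z = math.inf if absolute > 0 else -math.inf
    p = float(2 * stats.norm.sf(abs(z)))
    if r2.rate == 0:
        return RateContrast(absolute, math.nan, math.nan, math.nan, math.nan, z, p)
    relative = 100.0 * absolute / r2.rate
    ratio = r1.rate / r2.rate
    if r1.rate > 0:
        se_log = math.sqrt(r1.variance / r1.rate**2 + r2.variance / r2.rate**2)
        lo = ratio * math.exp(-_Z95 * se_log)
        hi = ratio * math.exp(_Z95 * se_log)
    else:
        lo = hi = 0.0
    return RateContrast(absolute, relative, ratio, lo, hi, z, p)


def temporal_change(rate_first: StandardizedRate, rate_last: StandardizedRate) -> RateContrast:
    """Change between two periods of the same stratum (last minus first)."""
    return contrast(rate_last, rate_first)
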