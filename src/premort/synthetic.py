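"""Synthetic mortality registry with a programmed deprivation gradient.

Emulates the structure the inequality analysis assumes: many small areas
with strongly skewed (lognormal) population sizes; a deprivation score per
area that is monotone in an unobserved area-level risk multiplier; Poisson
death counts per area x sex x single-year age (1-74) x calendar year, with
age-sex baseline rates, a log-linear risk gradient across deprivation
deciles (ratio ``target_rr`` between the most and least deprived), and a
multiplicative annual decline that is faster in the least deprived decile;
and an ICD-10 cause drawn per death with cause-specific decile tilts.

The generator runs in "known-truth" mode: alongside the records it returns
a :class:`SyntheticTruth` carrying the exact per-stratum expected deaths
and exposures over the analysis decile partition, from which the implied
(analytic) attributable fraction and standardized-rate ratios follow in
closed form — the oracle for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deprivation import DEFAULT_PERIOD_MAP, PeriodMap, assign_deciles, exclude_small_areas
from .rates import AGE_GROUPS, AGE_GROUP_LABELS, ESP2013_1_74, StandardPopulation

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "ConfigError",
    "DEFAULT_BASELINE",
    "DEFAULT_CAUSE_MIX",
    "generate_areas",
    "generate_registry",
    "analytic_paf_from_truth",
    "write_csvs",
]

SEXES = ("M", "F")
AGES = np.arange(1, 75)


class ConfigError(ValueError):
    pass


def _schedule(per_100k_m: list[float], per_100k_f: list[float]) -> dict:
    out = {}
    for label, rm, rf in zip(AGE_GROUP_LABELS, per_100k_m, per_100k_f):
        out[(label, "M")] = rm / 1e5
        out[(label, "F")] = rf / 1e5
    return out


#: Least-deprived-decile annual death rates in the first simulated year,
#: per age group and sex.  Chosen so the least-deprived standardized rate
#: lands near 490 (men) / 245 (women) per 100,000 person-years — the order
#: of magnitude of late-1990s western-European premature mortality.
DEFAULT_BASELINE = _schedule(
    per_100k_m=[18, 8, 10, 40, 65, 70, 80, 110, 170, 280, 460, 700, 1150, 1800, 2800],
    per_100k_f=[14, 6, 7, 15, 22, 26, 35, 55, 90, 150, 240, 370, 580, 900, 1400],
)

#: Cause mix: 3-character ICD-10 category -> (share of deaths, decile tilt).
#: The tilt is the most/least-deprived ratio of the cause's share; strongly
#: deprivation-linked causes (COPD, liver disease) tilt hardest, breast
#: cancer essentially not at all.  "R99" absorbs the remaining causes.
DEFAULT_CAUSE_MIX: dict[str, tuple[float, float]] = {
    "I21": (0.07, 1.6),   # acute myocardial infarction
    "I25": (0.04, 1.6),   # chronic ischaemic heart disease
    "C34": (0.11, 1.6),   # lung cancer
    "C18": (0.07, 1.2),   # colon cancer
    "J44": (0.05, 3.2),   # COPD
    "I64": (0.05, 1.7),   # stroke
    "K70": (0.04, 2.9),   # alcoholic liver disease
    "X70": (0.06, 1.9),   # intentional self-harm
    "V43": (0.05, 2.1),   # transport accident
    "J18": (0.03, 1.9),   # pneumonia
    "C50": (0.05, 0.95),  # breast cancer
    "C56": (0.03, 1.1),   # ovarian cancer
    "R99": (0.35, 1.0),   # other / ill-defined
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic registry.

    Defaults emulate the full-scale setting: ~18,000 small areas with a
    population median near 344 (quartiles ~133/759), a most/least
    all-cause rate ratio of 2, and annual rate declines of 1.8% (most
    deprived) and 2.8% (least deprived) over 1998-2019.
    """

    n_areas: int = 18000
    area_size_log_mean: float = 5.84
    area_size_log_sd: float = 1.30
    years: tuple[int, int] = (1998, 2019)
    baseline_schedule: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    cause_mix: dict = field(default_factory=lambda: dict(DEFAULT_CAUSE_MIX))
    target_rr: float = 2.0
    annual_decline_most: float = 0.018
    annual_decline_least: float = 0.028
    seed: int = 0

    def validate(self) -> None:
        if self.n_areas < 10:
            raise ConfigError("n_areas must be at least 10 (one area per decile)")
        if self.area_size_log_sd < 0:
            raise ConfigError("area_size_log_sd must be nonnegative")
        if self.target_rr < 1:
            raise ConfigError("target_rr must be >= 1 (decile 1 at least as deadly)")
        if not (0 <= self.annual_decline_most < 1 and 0 <= self.annual_decline_least < 1):
            raise ConfigError("annual declines must lie in [0, 1)")
        if self.years[1] < self.years[0]:
            raise ConfigError("empty year range")
        psum = sum(p for p, _ in self.cause_mix.values())
        if abs(psum - 1.0) > 1e-9:
            raise ConfigError(f"cause_mix proportions sum to {psum}, not 1")
        for (label, sex), r in self.baseline_schedule.items():
            if r < 0:
                raise ConfigError(f"negative baseline rate for {(label, sex)}")
        max_rate = max(self.baseline_schedule.values(), default=0.0) * self.target_rr
        if max_rate > 1:
            raise ConfigError("true death rate exceeds 1 per person-year")


def _decile_multipliers(cfg: GeneratorConfig) -> np.ndarray:
    """Risk multiplier per decile 1..10, log-linear between rr and 1."""
    d = np.arange(1, 11)
    return cfg.target_rr ** ((10 - d) / 9)


def _trend_logs(cfg: GeneratorConfig) -> np.ndarray:
    """Per-decile log of the annual multiplicative trend, log-linear
    between the most- and least-deprived extremes."""
    d = np.arange(1, 11)
    frac_most = (10 - d) / 9
    return frac_most * np.log1p(-cfg.annual_decline_most) + (1 - frac_most) * np.log1p(
        -cfg.annual_decline_least
    )


def generate_areas(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Area table: integer id, lognormal population, deprivation score.

    The score is the area's latent risk percentile, so ranking areas by
    score reproduces the programmed risk ordering exactly.  Deterministic
    given the config seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng([int(config.seed) % (2**31), 11])
    pop = np.round(
        rng.lognormal(config.area_size_log_mean, config.area_size_log_sd, config.n_areas)
    ).astype(np.int64)
    risk_pct = rng.uniform(size=config.n_areas)
    return pd.DataFrame(
        {
            "area_id": np.arange(1, config.n_areas + 1, dtype=np.int64),
            "population": pop,
            "score": risk_pct,
        }
    )


def _base_rate_by_age(cfg: GeneratorConfig) -> np.ndarray:
    """(2, 74) baseline rate per sex index (0=M, 1=F) and single age."""
    group_idx = np.searchsorted([g[0] for g in AGE_GROUPS], AGES, side="right") - 1
    out = np.empty((2, len(AGES)))
    for si, sex in enumerate(SEXES):
        per_group = np.array([cfg.baseline_schedule[(lab, sex)] for lab in AGE_GROUP_LABELS])
        out[si] = per_group[group_idx]
    return out


@dataclass
class SyntheticTruth:
    """Exact per-stratum expectations behind a generated registry.

    ``strata`` has one row per decile x sex x age group x period over the
    analysis universe (areas retained after the small-population
    exclusion) with the programmed expected deaths and person-years.
    """

    strata: pd.DataFrame
    expected_total_deaths: float
    analytic_paf: float | None
    target_rr: float

    def analytic_asmr(
        self, decile: int, sex: str, period: str | None = None,
        standard: StandardPopulation = ESP2013_1_74,
    ) -> float:
        """Standardized rate implied by the programmed rates (per 100,000)."""
        df = self.strata[(self.strata["decile"] == decile) & (self.strata["sex"] == sex)]
        if period is not None:
            df = df[df["period"] == period]
        agg = df.groupby("age_group", observed=True)[["deaths", "person_years"]].sum()
        w = standard.as_series()
        agg = agg.reindex(w.index).fillna(0.0)
        r = np.divide(
            agg["deaths"], agg["person_years"],
            out=np.zeros(len(agg)), where=agg["person_years"] > 0,
        )
        return 1e5 * float((w.to_numpy() * r).sum()) / float(w.sum())

    def analytic_ratio(self, sex: str, period: str | None = None) -> float:
        """Implied most/least-deprived standardized-rate ratio."""
        return self.analytic_asmr(1, sex, period) / self.analytic_asmr(10, sex, period)


def analytic_paf_from_truth(strata: pd.DataFrame, reference_decile: int = 10) -> float | None:
    """Closed-form attributable fraction from expected counts and exposures.

    Reference rates per (sex, age group, period) cell come from the
    reference decile's expected deaths over its person-years and are
    applied to every decile's person-years; PAF = 1 - expected/observed.
    Returns None (undefined) when there are no expected deaths at all.
    """
    total = float(strata["deaths"].sum())
    if total == 0:
        return None
    keys = [k for k in ("sex", "age_group", "period") if k in strata.columns]
    ref = strata[strata["decile"] == reference_decile]
    refagg = ref.groupby(keys, observed=True).agg(
        rd=("deaths", "sum"), rpy=("person_years", "sum")
    )
    m = strata.merge(refagg, on=keys, how="left")
    expected = float((m["rd"] / m["rpy"] * m["person_years"]).sum())
    return 1.0 - expected / total


def _restrict_period_map(period_map: PeriodMap, years: tuple[int, int]) -> pd.DataFrame:
    lookup = period_map.lookup()
    lookup = lookup[(lookup["year"] >= years[0]) & (lookup["year"] <= years[1])]
    missing = set(range(years[0], years[1] + 1)) - set(lookup["year"])
    if missing:
        raise ConfigError(f"simulated years not covered by the period map: {sorted(missing)}")
    return lookup


def generate_registry(
    config: GeneratorConfig,
    areas: pd.DataFrame | None = None,
    period_map: PeriodMap = DEFAULT_PERIOD_MAP,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Individual death records, population table, and the known truth.

    Death counts per area x sex x single-year age x year are Poisson with
    mean = population x programmed rate; each death becomes one record
    with an ICD-10 category drawn from the (decile-tilted) cause mix.
    Populations are constant over calendar years (no migration is
    simulated).  Deterministic given the config seed.
    """
    config.validate()
    if areas is None:
        areas = generate_areas(config)
    areas = areas.sort_values("area_id", kind="mergesort").reset_index(drop=True)
    rng = np.random.default_rng([int(config.seed) % (2**31), 22])
    years = np.arange(config.years[0], config.years[1] + 1)
    lookup = _restrict_period_map(period_map, config.years)
    n_areas = len(areas)

    # Truth deciles: exactly the partition the analysis will recover
    # (small-population exclusion, then ranked scores).
    retained, _ = exclude_small_areas(areas, threshold=10)
    assignment = assign_deciles(retained, vintage="truth")
    dec_map = assignment.set_index("area_id")["decile"]
    dec = areas["area_id"].map(dec_map).fillna(10).astype(int).to_numpy()
    retained_mask = areas["area_id"].isin(retained["area_id"]).to_numpy()

    # Population allocation: each area's inhabitants spread uniformly over
    # 2 sexes x 74 single-year ages, one multinomial draw per area.
    K = 2 * len(AGES)
    cells = rng.multinomial(
        areas["population"].to_numpy().astype(np.int64), np.full(K, 1.0 / K)
    )
    cells = cells.reshape(n_areas, 2, len(AGES))

    base = _base_rate_by_age(config)                        # (2, 74)
    mult = _decile_multipliers(config)                      # (10,)
    trend_log = _trend_logs(config)                         # (10,)
    di = dec - 1

    rec_age, rec_sex, rec_year, rec_area = [], [], [], []
    expected_total = 0.0
    # truth accumulator: expected deaths per (decile, sex, age, year), retained areas only
    P_truth = np.zeros((10, 2, len(AGES)))
    np.add.at(P_truth, di[retained_mask], cells[retained_mask])

    for t, year in enumerate(years):
        decay = np.exp(trend_log * t)                       # (10,)
        rate_dsa = base[None, :, :] * (mult * decay)[:, None, None]   # (10, 2, 74)
        if rate_dsa.max() > 1:
            raise ConfigError("true death rate exceeds 1 per person-year")
        lam = cells * rate_dsa[di]                          # (n_areas, 2, 74)
        expected_total += float(lam.sum())
        draws = rng.poisson(lam)
        a_idx, s_idx, x_idx = np.nonzero(draws)
        counts = draws[a_idx, s_idx, x_idx]
        rec_age.append(np.repeat(AGES[x_idx], counts))
        rec_sex.append(np.repeat(s_idx, counts))
        rec_year.append(np.full(int(counts.sum()), year, dtype=np.int16))
        rec_area.append(np.repeat(areas["area_id"].to_numpy()[a_idx], counts))

    age_arr = np.concatenate(rec_age) if rec_age else np.array([], dtype=int)
    sex_arr = np.concatenate(rec_sex) if rec_sex else np.array([], dtype=int)
    year_arr = np.concatenate(rec_year) if rec_year else np.array([], dtype=int)
    area_arr = np.concatenate(rec_area) if rec_area else np.array([], dtype=int)

    # cause draw, decile-tilted, in fixed decile order for determinism
    codes = np.array(list(config.cause_mix.keys()))
    p = np.array([v[0] for v in config.cause_mix.values()])
    tilt = np.array([v[1] for v in config.cause_mix.values()])
    dec_of_death = dec[np.searchsorted(areas["area_id"].to_numpy(), area_arr)]
    icd = np.empty(len(age_arr), dtype=object)
    for d in range(1, 11):
        mask = dec_of_death == d
        if not mask.any():
            continue
        w = p * tilt ** ((10 - d) / 9)
        w = w / w.sum()
        icd[mask] = rng.choice(codes, size=int(mask.sum()), p=w)

    deaths = pd.DataFrame(
        {
            "age": age_arr.astype(np.int16),
            "sex": pd.Categorical.from_codes(sex_arr, categories=list(SEXES)),
            "year": year_arr.astype(np.int16),
            "area_id": area_arr.astype(np.int64),
            "icd10": icd,
        }
    )

    # population table: one row per area x sex x age x year
    block_area = np.repeat(areas["area_id"].to_numpy(), K)
    block_sex = np.tile(np.repeat(np.arange(2), len(AGES)), n_areas)
    block_age = np.tile(np.tile(AGES, 2), n_areas)
    block_count = cells.reshape(-1)
    n_years = len(years)
    populations = pd.DataFrame(
        {
            "area_id": np.tile(block_area, n_years),
            "sex": pd.Categorical.from_codes(
                np.tile(block_sex, n_years), categories=list(SEXES)
            ),
            "age": np.tile(block_age, n_years).astype(np.int16),
            "year": np.repeat(years, len(block_area)).astype(np.int16),
            "count": np.tile(block_count, n_years).astype(np.int64),
        }
    )

    truth = _build_truth(config, P_truth, years, lookup)
    truth_obj = SyntheticTruth(
        strata=truth,
        expected_total_deaths=expected_total,
        analytic_paf=analytic_paf_from_truth(truth),
        target_rr=config.target_rr,
    )
    return deaths, populations, truth_obj


def _build_truth(
    cfg: GeneratorConfig, P_truth: np.ndarray, years: np.ndarray, lookup: pd.DataFrame
) -> pd.DataFrame:
    """Expected deaths and person-years per decile/sex/age-group/period."""
    base = _base_rate_by_age(cfg)
    mult = _decile_multipliers(cfg)
    trend_log = _trend_logs(cfg)
    group_idx = np.searchsorted([g[0] for g in AGE_GROUPS], AGES, side="right") - 1
    period_of_year = dict(zip(lookup["year"], lookup["period"]))

    rows = []
    periods = {}
    for t, year in enumerate(years):
        decay = np.exp(trend_log * t)
        rate_dsa = base[None, :, :] * (mult * decay)[:, None, None]
        mean_dsa = P_truth * rate_dsa
        periods.setdefault(period_of_year[int(year)], []).append(mean_dsa)
    for period, means in periods.items():
        mean = np.sum(means, axis=0)
        n_years = len(means)
        for d in range(10):
            for si, sex in enumerate(SEXES):
                for gi, label in enumerate(AGE_GROUP_LABELS):
                    sel = group_idx == gi
                    rows.append(
                        {
                            "decile": d + 1,
                            "sex": sex,
                            "age_group": label,
                            "period": period,
                            "deaths": float(mean[d, si, sel].sum()),
                            "person_years": float(P_truth[d, si, sel].sum()) * n_years,
                        }
                    )
    return pd.DataFrame(rows)


def write_csvs(
    outdir: str | Path,
    deaths: pd.DataFrame,
    populations: pd.DataFrame,
    areas: pd.DataFrame,
) -> None:
    """Write deaths.csv, population.csv and areas.csv (UTF-8, '.' decimal)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    deaths.to_csv(outdir / "deaths.csv", index=False)
    populations.to_csv(outdir / "population.csv", index=False)
    areas.to_csv(outdir / "areas.csv", index=False)
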