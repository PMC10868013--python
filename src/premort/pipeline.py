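"""End-to-end orchestration: decile assignment -> cause grouping ->
standardized rates -> attributable fraction -> years of life lost,
with report tables and a stage-level run log."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import causes as cod
from . import paf as paf_mod
from . import pyll as pyll_mod
from . import rates as rates_mod
from .deprivation import (
    DEFAULT_PERIOD_MAP,
    PeriodMap,
    attach_decile_to_events,
    build_assignment,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_all", "rank_causes", "asmr_table"]

ALL_PERIODS = "1998-2019"


@dataclass
class RunConfig:
    """File-based configuration for a full run (fail-fast validated)."""

    deaths_path: str
    population_path: str
    areas_paths: dict[str, str]          # vintage -> areas csv
    out_dir: str = "premort_out"
    exclusion_threshold: int = 10
    cause_threshold: int = 1000
    reference_decile: int = 10
    iterations: int = 10000
    seed: int = 0
    candidates: list = field(default_factory=lambda: list(cod.DEFAULT_CANDIDATES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "candidates" in raw:
            raw["candidates"] = [tuple(c) for c in raw["candidates"]]
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.deaths_path, self.population_path, *self.areas_paths.values()]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


@dataclass
class PipelineResult:
    assignment: pd.DataFrame
    hierarchy: "cod.CauseHierarchy"
    strata: pd.DataFrame
    rates: pd.DataFrame
    table1: pd.DataFrame
    table23: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    pyll_national: pd.DataFrame
    log: dict


def asmr_table(strata: pd.DataFrame, standard=rates_mod.ESP2013_1_74) -> pd.DataFrame:
    """Standardized rate per (period, sex, decile, cause), including a
    pooled all-years period."""
    pooled = (
        strata.groupby(["sex", "decile", "cause", "age_group"], observed=True)[
            ["deaths", "person_years"]
        ]
        .sum()
        .reset_index()
    )
    pooled["period"] = ALL_PERIODS
    work = pd.concat([strata, pooled], ignore_index=True)
    rows = []
    for (period, sex, decile, cause), grp in work.groupby(
        ["period", "sex", "decile", "cause"], observed=True
    ):
        r = rates_mod.standardize(grp, standard)
        rows.append(
            {
                "period": period,
                "sex": sex,
                "decile": decile,
                "cause": cause,
                "asmr": r.rate,
                "var": r.variance,
                "lo": r.lo,
                "hi": r.hi,
                "deaths": r.deaths,
            }
        )
    return pd.DataFrame(rows)


def _sr(row) -> rates_mod.StandardizedRate:
    return rates_mod.StandardizedRate(
        rate=row["asmr"], variance=row["var"], lo=row["lo"], hi=row["hi"], deaths=row["deaths"]
    )


def _pick(rates: pd.DataFrame, **kv) -> rates_mod.StandardizedRate:
    m = pd.Series(True, index=rates.index)
    for k, v in kv.items():
        m &= rates[k] == v
    sub = rates[m]
    if len(sub) != 1:
        raise KeyError(f"expected exactly one rate row for {kv}, found {len(sub)}")
    return _sr(sub.iloc[0])


def rank_causes(
    rates: pd.DataFrame, sex: str, period: str, causes: list[str], decile: int = 1, k: int = 10
) -> list[str]:
    """Causes ordered by descending ASMR in the given scope; ties break by
    cause code for a stable order."""
    sub = rates[
        (rates["sex"] == sex)
        & (rates["period"] == period)
        & (rates["decile"] == decile)
        & (rates["cause"].isin(causes))
    ]
    sub = sub.sort_values(["asmr", "cause"], ascending=[False, True], kind="mergesort")
    return sub["cause"].head(k).tolist()


def _contrast_row(c: rates_mod.RateContrast) -> dict:
    return {
        "absolute": c.absolute,
        "relative_pct": c.relative_pct,
        "ratio": c.ratio,
        "ratio_lo": c.ratio_lo,
        "ratio_hi": c.ratio_hi,
        "z": c.z,
        "p": c.p,
    }


def run_pipeline(
    deaths: pd.DataFrame,
    populations: pd.DataFrame,
    areas_by_vintage: dict[str, pd.DataFrame],
    period_map: PeriodMap = DEFAULT_PERIOD_MAP,
    exclusion_threshold: int = 10,
    candidates=None,
    cause_threshold: int = 1000,
    standard=rates_mod.ESP2013_1_74,
    reference_decile: int = 10,
    iterations: int = 10000,
    seed: int = 0,
    top_k: int = 10,
) -> PipelineResult:
    """Run the full analysis on in-memory tables."""
    log: dict = {"seed": seed, "deaths_input": len(deaths)}

    # stage 1: deprivation assignment
    assignment = pd.concat(
        [
            build_assignment(areas_by_vintage[v], v, exclusion_threshold)
            for v in period_map.vintages
        ],
        ignore_index=True,
    )
    tagged = attach_decile_to_events(deaths, populations, assignment, period_map)
    log.update(tagged.report)

    # stage 2: cause hierarchy (gated on the analysis set, ages 1-74)
    in_age = tagged.deaths["age"].between(1, 74)
    log["deaths_rejected_age"] = int((~in_age).sum())
    d = tagged.deaths.loc[in_age].copy()
    d["icd10"] = cod.normalize_codes(d["icd10"])
    hierarchy = cod.build_hierarchy(d["icd10"], candidates, cause_threshold)
    chap = cod.chapter_of(d["icd10"])
    log["deaths_unclassified"] = int((chap == cod.UNCLASSIFIED).sum())

    # stage 3: strata and standardized rates
    strata = rates_mod.aggregate_strata(d, tagged.populations, hierarchy)
    rates = asmr_table(strata, standard)

    present = set(strata["period"].unique())
    periods = [p for p in period_map.labels if p in present]
    first, last = periods[0], periods[-1]
    sexes = sorted(d["sex"].astype(str).unique())

    # table 1: all-cause rates by decile extreme, with contrasts and changes
    t1_rows = []
    for sex in sexes:
        for period in periods + [ALL_PERIODS]:
            r1 = _pick(rates, sex=sex, period=period, decile=1, cause="ALL")
            r10 = _pick(rates, sex=sex, period=period, decile=reference_decile, cause="ALL")
            c = rates_mod.contrast(r1, r10)
            t1_rows.append(
                {
                    "sex": sex, "period": period,
                    "asmr_most": r1.rate, "most_lo": r1.lo, "most_hi": r1.hi,
                    "asmr_least": r10.rate, "least_lo": r10.lo, "least_hi": r10.hi,
                    **_contrast_row(c),
                }
            )
        for decile, tag in ((1, "most"), (reference_decile, "least")):
            ch = rates_mod.temporal_change(
                _pick(rates, sex=sex, period=first, decile=decile, cause="ALL"),
                _pick(rates, sex=sex, period=last, decile=decile, cause="ALL"),
            )
            t1_rows.append(
                {"sex": sex, "period": f"change_{tag}_{first}_to_{last}", **_contrast_row(ch)}
            )
    table1 = pd.DataFrame(t1_rows)

    # tables 2-3: top causes (level-2 nodes) most vs least deprived
    l2 = [n.node_id for n in hierarchy.level_nodes(2)]
    t23_rows = []
    for sex in sexes:
        top = rank_causes(rates, sex, first, l2, decile=1, k=top_k)
        for cause in top:
            for period in (first, last):
                r1 = _pick(rates, sex=sex, period=period, decile=1, cause=cause)
                r10 = _pick(rates, sex=sex, period=period, decile=reference_decile, cause=cause)
                c = rates_mod.contrast(r1, r10)
                t23_rows.append(
                    {
                        "sex": sex, "cause": cause, "period": period,
                        "asmr_most": r1.rate, "asmr_least": r10.rate,
                        **_contrast_row(c),
                    }
                )
            for decile, tag in ((1, "most"), (reference_decile, "least")):
                ch = rates_mod.temporal_change(
                    _pick(rates, sex=sex, period=first, decile=decile, cause=cause),
                    _pick(rates, sex=sex, period=last, decile=decile, cause=cause),
                )
                t23_rows.append(
                    {"sex": sex, "cause": cause, "period": f"change_{tag}", **_contrast_row(ch)}
                )
    table23 = pd.DataFrame(t23_rows)

    # table 4: attributable fraction by sex and period, plus pooled scopes
    allcause = strata[strata["cause"] == "ALL"].drop(columns=["cause"])
    scopes = []
    for sex in sexes:
        for period in periods:
            scopes.append(
                (f"{sex}|{period}", allcause[(allcause["sex"] == sex) & (allcause["period"] == period)])
            )
        scopes.append((f"{sex}|{ALL_PERIODS}", allcause[allcause["sex"] == sex]))
    scopes.append((f"total|{ALL_PERIODS}", allcause))
    children = np.random.SeedSequence(seed).spawn(len(scopes))
    t4_rows = []
    for (name, sub), child in zip(scopes, children):
        est = paf_mod.paf_mc_ui(
            sub, reference_decile, iterations=iterations, seed=child, scope=name
        )
        sex_name, period_name = name.split("|")
        t4_rows.append(
            {
                "sex": sex_name, "period": period_name,
                "observed": est.observed, "expected": est.expected,
                "attributable": est.attributable,
                "paf_pct": est.paf_pct,
                "ui_lo_pct": 100 * est.ui_lo, "ui_hi_pct": 100 * est.ui_hi,
                "iterations": iterations, "seed": seed,
            }
        )
    table4 = pd.DataFrame(t4_rows)
    for sex in sexes:
        sub = table4[table4["sex"] == sex].set_index("period")
        p1, p4 = sub.loc[first, "paf_pct"], sub.loc[last, "paf_pct"]
        table4.loc[len(table4)] = {
            "sex": sex, "period": f"rel_diff_{first}_to_{last}",
            "paf_pct": 100.0 * (p4 - p1) / p1,
        }

    # table 5 + national PYLL decomposition
    decomp = pyll_mod.pyll_decomposition(
        d, tagged.populations, reference_decile, by=["sex", "period"]
    )
    nat_rows = []
    for sex in sexes:
        sub = decomp[decomp["sex"] == sex]
        nat_rows.append(
            {
                "sex": sex,
                "observed": float(sub["observed"].sum()),
                "expected": float(sub["expected"].sum()),
                "excess": float(sub["excess"].sum()),
                "share_pct": 100.0 * sub["excess"].sum() / sub["observed"].sum(),
            }
        )
    pyll_national = pd.DataFrame(nat_rows)

    aspyll = pyll_mod.standardized_pyll(d, tagged.populations, standard, by=["sex", "period", "decile"])
    aspyll_all = pyll_mod.standardized_pyll(d, tagged.populations, standard, by=["sex", "decile"])
    aspyll_all["period"] = ALL_PERIODS
    aspyll = pd.concat([aspyll, aspyll_all[aspyll.columns]], ignore_index=True)
    t5_rows = []
    for sex in sexes:
        for period in periods + [ALL_PERIODS]:
            sub = aspyll[(aspyll["sex"] == sex) & (aspyll["period"] == period)].set_index("decile")
            most, least = float(sub.loc[1, "aspyll"]), float(sub.loc[reference_decile, "aspyll"])
            t5_rows.append(
                {
                    "sex": sex, "period": period,
                    "aspyll_most": most, "aspyll_least": least,
                    "absolute": least - most,
                    "relative_pct": 100.0 * (least - most) / most,
                }
            )
        sub = pd.DataFrame(t5_rows)
        for decile_col, tag in (("aspyll_most", "most"), ("aspyll_least", "least")):
            row_f = sub[(sub["sex"] == sex) & (sub["period"] == first)].iloc[0]
            row_l = sub[(sub["sex"] == sex) & (sub["period"] == last)].iloc[0]
            t5_rows.append(
                {
                    "sex": sex, "period": f"change_{tag}_{first}_to_{last}",
                    "absolute": row_l[decile_col] - row_f[decile_col],
                    "relative_pct": 100.0 * (row_l[decile_col] - row_f[decile_col]) / row_f[decile_col],
                }
            )
    table5 = pd.DataFrame(t5_rows)

    log["strata_rows"] = len(strata)
    log["conservation_ok"] = bool(
        log["deaths_in"] + log["deaths_excluded"] + log["deaths_unassigned"]
        == log["deaths_total"]
    )
    return PipelineResult(
        assignment=assignment,
        hierarchy=hierarchy,
        strata=strata,
        rates=rates,
        table1=table1,
        table23=table23,
        table4=table4,
        table5=table5,
        pyll_national=pyll_national,
        log=log,
    )


def run_all(config: RunConfig) -> PipelineResult:
    """Read inputs, run the pipeline, write report CSVs and a run log."""
    config.validate()
    deaths = pd.read_csv(config.deaths_path)
    populations = pd.read_csv(config.population_path)
    areas = {v: pd.read_csv(p) for v, p in config.areas_paths.items()}
    result = run_pipeline(
        deaths,
        populations,
        areas,
        exclusion_threshold=config.exclusion_threshold,
        candidates=config.candidates,
        cause_threshold=config.cause_threshold,
        reference_decile=config.reference_decile,
        iterations=config.iterations,
        seed=config.seed,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.assignment.to_csv(out / "assignment.csv", index=False)
    result.hierarchy.to_frame().to_csv(out / "hierarchy.csv", index=False)
    result.rates.to_csv(out / "rates.csv", index=False)
    result.table1.to_csv(out / "table1_rates.csv", index=False)
    result.table23.to_csv(out / "table23_causes.csv", index=False)
    result.table4.to_csv(out / "table4_paf.csv", index=False)
    result.table5.to_csv(out / "table5_aspyll.csv", index=False)
    result.pyll_national.to_csv(out / "pyll_national.csv", index=False)
    with open(out / "run_log.txt", "w") as fh:
        for k, v in result.log.items():
            fh.write(f"{k}: {v}\n")
    return result
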