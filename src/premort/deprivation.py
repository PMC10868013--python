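"""Deprivation-decile assignment of small areas and period-to-vintage mapping.

Areas (statistical sectors) carry a composite deprivation score per index
vintage.  After excluding areas with very small populations, scores are
ranked — highest deprivation first — and split into ten equal-count deciles:
decile 1 is the most deprived, decile 10 the least deprived and serves as
the counterfactual reference downstream.  Calendar years map to the index
vintage in force for that period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PeriodSpec",
    "PeriodMap",
    "DEFAULT_PERIOD_MAP",
    "ExclusionError",
    "exclude_small_areas",
    "assign_deciles",
    "build_assignment",
    "attach_decile_to_events",
    "TaggedEvents",
]


class ExclusionError(ValueError):
    pass


@dataclass(frozen=True)
class PeriodSpec:
    label: str
    start: int
    end: int      # inclusive
    vintage: str


@dataclass(frozen=True)
class PeriodMap:
    """Ordered, disjoint calendar periods, each tied to an index vintage."""

    periods: tuple[PeriodSpec, ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.periods, key=lambda p: p.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping periods {a.label} and {b.label}")

    def lookup(self) -> pd.DataFrame:
        """One row per calendar year: year, period, vintage."""
        rows = [
            {"year": y, "period": p.label, "vintage": p.vintage}
            for p in self.periods
            for y in range(p.start, p.end + 1)
        ]
        return pd.DataFrame(rows)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in sorted(self.periods, key=lambda p: p.start)]

    @property
    def vintages(self) -> list[str]:
        seen: list[str] = []
        for p in sorted(self.periods, key=lambda p: p.start):
            if p.vintage not in seen:
                seen.append(p.vintage)
        return seen


DEFAULT_PERIOD_MAP = PeriodMap(
    (
        PeriodSpec("1998-2003", 1998, 2003, "2001"),
        PeriodSpec("2004-2008", 2004, 2008, "2001"),
        PeriodSpec("2009-2013", 2009, 2013, "2011"),
        PeriodSpec("2014-2019", 2014, 2019, "2011"),
    )
)


def exclude_small_areas(
    areas: pd.DataFrame, threshold: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition areas into (retained, excluded) by the population cut-off.

    Areas with population less than or equal to ``threshold`` inhabitants
    are excluded — small populations give unreliable rates and raise
    privacy concerns.  Returns copies; the excluded frame carries a
    ``reason`` column.
    """
    if "population" not in areas.columns:
        raise ExclusionError("areas table lacks a 'population' column")
    pop = areas["population"]
    if pop.isna().any() or (pop < 0).any():
        raise ExclusionError("area populations must be present and nonnegative")
    mask = pop <= threshold
    excluded = areas.loc[mask].copy()
    excluded["reason"] = f"population <= {threshold}"
    return areas.loc[~mask].copy(), excluded


def assign_deciles(areas: pd.DataFrame, vintage: str) -> pd.DataFrame:
    """Rank retained areas by deprivation score and cut into ten deciles.

    Higher scores mean higher deprivation and rank first (decile 1).  Ties
    break by area id so the assignment is stable under input permutation.
    When the number of areas is not a multiple of ten, the remainder goes to
    the lowest-numbered (most deprived) deciles, so decile sizes differ by
    at most one.
    """
    if len(areas) < 10:
        raise ValueError(f"need at least 10 areas to form deciles, got {len(areas)}")
    if not pd.api.types.is_numeric_dtype(areas["score"]):
        raise ValueError("deprivation scores must be numeric")
    ranked = areas.sort_values(
        ["score", "area_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    n = len(ranked)
    q, r = divmod(n, 10)
    sizes = [q + 1 if d <= r else q for d in range(1, 11)]
    deciles = []
    for d, size in enumerate(sizes, start=1):
        deciles.extend([d] * size)
    out = pd.DataFrame(
        {
            "area_id": ranked["area_id"].to_numpy(),
            "vintage": vintage,
            "decile": pd.array(deciles, dtype="int64"),
            "excluded": False,
            "reason": "",
        }
    )
    return out.sort_values("area_id", kind="mergesort").reset_index(drop=True)


def build_assignment(
    areas: pd.DataFrame, vintage: str, threshold: int = 10
) -> pd.DataFrame:
    """Exclusion + decile ranking in one step; excluded areas keep a row."""
    retained, excluded = exclude_small_areas(areas, threshold)
    assignment = assign_deciles(retained, vintage)
    if len(excluded):
        excl_rows = pd.DataFrame(
            {
                "area_id": excluded["area_id"].to_numpy(),
                "vintage": vintage,
                "decile": pd.NA,
                "excluded": True,
                "reason": excluded["reason"].to_numpy(),
            }
        )
        assignment = pd.concat([assignment, excl_rows], ignore_index=True)
        assignment = assignment.sort_values("area_id", kind="mergesort").reset_index(drop=True)
    return assignment


@dataclass
class TaggedEvents:
    """Decile/period-tagged analysis tables plus the routing report.

    Conservation: for each input table, rows in + excluded + unassigned
    equals the input total.
    """

    deaths: pd.DataFrame
    populations: pd.DataFrame
    deaths_excluded: pd.DataFrame
    deaths_unassigned: pd.DataFrame
    report: dict = field(default_factory=dict)


def _tag(events: pd.DataFrame, assignment: pd.DataFrame, period_map: PeriodMap):
    lookup = period_map.lookup()
    years = set(lookup["year"])
    bad_years = sorted(set(events["year"].unique()) - years)
    if bad_years:
        raise ValueError(f"event years outside every configured period: {bad_years}")
    tagged = events.merge(lookup, on="year", how="left")
    tagged = tagged.merge(
        assignment[["area_id", "vintage", "decile", "excluded"]],
        on=["area_id", "vintage"],
        how="left",
    )
    unassigned = tagged[tagged["excluded"].isna()].drop(columns=["decile", "excluded"])
    excluded = tagged[tagged["excluded"] == True]  # noqa: E712
    kept = tagged[tagged["excluded"] == False].drop(columns=["excluded"])  # noqa: E712
    kept = kept.astype({"decile": "int64"})
    return kept, excluded, unassigned


def attach_decile_to_events(
    deaths: pd.DataFrame,
    populations: pd.DataFrame,
    assignment: pd.DataFrame,
    period_map: PeriodMap = DEFAULT_PERIOD_MAP,
) -> TaggedEvents:
    """Tag deaths and population rows with (period, decile).

    The vintage active for each event's year selects the assignment.  Rows
    in excluded areas are dropped but counted; rows whose area is absent
    from the assignment are routed to an 'unassigned' report, never
    silently dropped.
    """
    d_kept, d_excl, d_un = _tag(deaths, assignment, period_map)
    p_kept, p_excl, p_un = _tag(populations, assignment, period_map)
    report = {
        "deaths_in": len(d_kept),
        "deaths_excluded": len(d_excl),
        "deaths_unassigned": len(d_un),
        "deaths_total": len(deaths),
        "population_rows_in": len(p_kept),
        "population_rows_excluded": len(p_excl),
        "population_rows_unassigned": len(p_un),
        "person_years_excluded": float(p_excl["count"].sum()) if len(p_excl) else 0.0,
    }
    return TaggedEvents(
        deaths=d_kept,
        populations=p_kept,
        deaths_excluded=d_excl,
        deaths_unassigned=d_un,
        report=report,
    )
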