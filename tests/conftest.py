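import numpy as np
import pandas as pd
import pytest

import premort as pm

ONE_PERIOD = pm.PeriodMap((pm.PeriodSpec("1998-2003", 1998, 2003, "2001"),))


def toy_strata(d1_deaths=50, d10_deaths=20, py=10_000, scale=1):
    """Two-decile, one-cell strata table: the hand-computable PAF toy."""
    return pd.DataFrame(
        {
            "period": ["1998-2003"] * 2,
            "sex": ["M"] * 2,
            "age_group": ["60-64"] * 2,
            "decile": [1, 10],
            "deaths": [d1_deaths * scale, d10_deaths * scale],
            "person_years": [py * scale, py * scale],
        }
    )


def null_strata(n_deciles=10, deaths=40, py=10_000):
    """Identical rates in every decile: zero-gradient strata."""
    return pd.DataFrame(
        {
            "period": ["1998-2003"] * n_deciles,
            "sex": ["M"] * n_deciles,
            "age_group": ["60-64"] * n_deciles,
            "decile": list(range(1, n_deciles + 1)),
            "deaths": [deaths] * n_deciles,
            "person_years": [py] * n_deciles,
        }
    )


@pytest.fixture(scope="session")
def small_registry():
    """One-period 400-area synthetic registry with known truth."""
    cfg = pm.GeneratorConfig(n_areas=400, years=(1998, 2003), seed=7)
    areas = pm.generate_areas(cfg)
    deaths, populations, truth = pm.generate_registry(cfg, areas, period_map=ONE_PERIOD)
    return cfg, areas, deaths, populations, truth


@pytest.fixture(scope="session")
def small_tagged(small_registry):
    """The small registry with deciles and periods attached."""
    _, areas, deaths, populations, _ = small_registry
    assignment = pm.build_assignment(areas, "2001", threshold=10)
    return pm.attach_decile_to_events(deaths, populations, assignment, ONE_PERIOD)


def allcause_strata(tagged):
    strata = pm.aggregate_strata(tagged.deaths, tagged.populations)
    return strata[strata["cause"] == "ALL"].drop(columns=["cause"])
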