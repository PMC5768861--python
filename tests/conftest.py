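import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import disturbkit as dk

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def normal_force() -> dk.ForceSeries:
    """200 seeded draws from N(10, 2), aggregate-type, upper tail harmful."""
    rng = np.random.default_rng(42)
    return dk.ForceSeries(
        years=np.arange(1800, 2000),
        values=rng.normal(10.0, 2.0, size=200),
        measure_kind="aggregate",
        harmful_tail="upper",
    )


@pytest.fixture
def lognormal_force() -> dk.ForceSeries:
    """200 seeded lognormal draws: raw values fail normality, logs pass."""
    rng = np.random.default_rng(7)
    return dk.ForceSeries(
        years=np.arange(1800, 2000),
        values=np.exp(rng.normal(1.0, 0.8, size=200)),
        measure_kind="aggregate",
        harmful_tail="upper",
    )


def make_abundance(
    abundances,
    event_year,
    start_year=2000,
    seasons=None,
    **kwargs,
) -> dk.AbundanceSeries:
    """Build an AbundanceSeries from a plain list of annual abundances."""
    years = np.arange(start_year, start_year + len(abundances))
    data = {"year": years, "abundance": abundances}
    if seasons is not None:
        data["season"] = seasons
    return dk.AbundanceSeries(
        data=pd.DataFrame(data), species_id="test", event_year=event_year, **kwargs
    )


def make_growth_series(normal_rates, r_pd) -> dk.GrowthRateSeries:
    """Build a GrowthRateSeries directly from normal-condition rates."""
    rows = [
        {"start_year": 2000 + i, "r": r, "status": dk.IntervalStatus.NORMAL}
        for i, r in enumerate(normal_rates)
    ]
    rows.append(
        {
            "start_year": 2000 + len(normal_rates),
            "r": r_pd,
            "status": dk.IntervalStatus.DISTURBANCE_YEAR,
        }
    )
    return dk.GrowthRateSeries(intervals=pd.DataFrame(rows), r_pd=r_pd)


@pytest.fixture
def worked_growth_series() -> dk.GrowthRateSeries:
    """Five normal rates (mean 0, sd 0.1581) and a -0.3 disturbance rate."""
    return make_growth_series([0.1, -0.1, 0.2, -0.2, 0.0], -0.3)
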