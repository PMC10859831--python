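import numpy as np
import pytest

from uroflow import CohortParams, Grid, Scenario, default_grid


@pytest.fixture
def base_params() -> CohortParams:
    return CohortParams()


def make_scenario(
    label: str = "toy",
    model: str = "prostate",
    annual: float = 500.0,
    rate: float | None = 1.1,
    target: float | None = None,
    **kwargs,
) -> Scenario:
    return Scenario(
        label=label,
        model=model,
        cohort=CohortParams(annual_referrals=annual),
        capacity_rate=rate,
        target_tww=target,
        **kwargs,
    )


@pytest.fixture
def congested_scenario() -> Scenario:
    # demand ~1.37/day against 1.1 slots/day: a large share of breaches
    return make_scenario()


@pytest.fixture
def toy_grid(congested_scenario) -> Grid:
    return Grid(scenarios=[congested_scenario])


@pytest.fixture(scope="session")
def calibrated_default_grid() -> Grid:
    grid = default_grid()
    for s in grid.scenarios:
        s.schedule()
    return grid
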