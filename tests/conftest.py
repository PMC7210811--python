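"""Shared fixtures: simulated experiments reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from germtt import (
    DishSpec,
    SimulationParams,
    TempSeriesParams,
    make_paper_design,
    simulate_germination_experiment,
    simulate_soil_temperature,
)


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams(rng_seed=0)


@pytest.fixture(scope="session")
def paper_records(default_params):
    """Full factorial experiment (2 sites x 5 pretreatments x 6 temps x 4 dishes)."""
    return simulate_germination_experiment(make_paper_design(), default_params)


@pytest.fixture(scope="session")
def recovery_setup():
    """Large sub-optimal-range experiment with known ground truth.

    One fully released seed lot (stratified far past the dormancy logistic),
    four sub-optimal incubation temperatures, 10,000 seeds per temperature,
    quarter-day scoring: the regime in which the rate-temperature relation
    should recover T_b and theta50.
    """
    params = SimulationParams(
        T_b_true=0.0,
        theta50_true=120.0,
        sigma_theta=0.15,
        schedule=tuple(np.arange(0.25, 120.25, 0.25)),
        rng_seed=0,
    )
    design = [
        DishSpec("SY", 365, temp, f"D{d}", n_seeds=2500)
        for temp in (5.0, 10.0, 15.0, 20.0)
        for d in range(1, 5)
    ]
    return params, design


@pytest.fixture(scope="session")
def recovery_records(recovery_setup):
    params, design = recovery_setup
    return simulate_germination_experiment(design, params)


@pytest.fixture(scope="session")
def soil_series():
    """Three-year mountain soil-logger series starting 01 Aug."""
    return simulate_soil_temperature(TempSeriesParams(rng_seed=0), site="IS")
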