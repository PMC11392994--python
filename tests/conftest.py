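import numpy as np
import pytest
from hypothesis import settings

from antforage.config import ContinuumParams, ScenarioConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """10x10 lattice with one food source, Table-value pheromone parameters."""
    return ScenarioConfig(
        M=10, N=10, n=20, x0=(3, 3), food_sources=[(8, 8)], T_max=20, seed=7
    )


@pytest.fixture
def foodless_config():
    return ScenarioConfig(M=15, N=15, n=10, x0=(8, 8), food_sources=[], T_max=10, seed=3)


@pytest.fixture
def pde_params():
    """Small continuum domain with one source offset from the central nest."""
    return ContinuumParams(
        Lx=16.0,
        Ly=16.0,
        x0=(8.0, 8.0),
        food_sources=[(12.0, 8.0)],
        h=0.5,
        dt=0.01,
    )
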