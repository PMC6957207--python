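"""Shared fixtures for the test suite.

All stochastic tests are seeded; hypothesis runs derandomised so the suite
is reproducible run-to-run.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from camkiisim.rates import Pools, RateTable

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rates() -> RateTable:
    return RateTable()


@pytest.fixture
def small_pools() -> Pools:
    return Pools(free_apo_cam=0, free_cam4=5, free_pp=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


#: A tamed conformational flicker (same stationary open probability as the
#: published 2e4 / 1e7 pair, 1000x slower) used where an engine must resolve
#: the flicker explicitly within a test budget.
@pytest.fixture
def tame_rates() -> RateTable:
    return RateTable(k_activate=20.0, k_inactivate=1.0e4)
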