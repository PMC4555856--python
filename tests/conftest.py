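import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from targetpunish import (
    DynamicsParams,
    StrategyRule,
    build_linear_profile,
)


@pytest.fixture(scope="session")
def profile200():
    return build_linear_profile(200)


@pytest.fixture(scope="session")
def profile6():
    return build_linear_profile(6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


ALL_RULES = [
    StrategyRule("uniform"),
    StrategyRule("single_file"),
    StrategyRule("groups", group_size=3, threshold=2 / 3),
    StrategyRule("groups", group_size=4, threshold=0.8),
]

ALL_POOLS = [
    DynamicsParams(beta=1.3, pi_cap=0.7, pool="cooperators"),
    DynamicsParams(beta=1.3, pi_cap=0.7, pool="all"),
    DynamicsParams(beta=1.3, pi_cap=0.7, pool="fraction", punishing_fraction=0.6),
]
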