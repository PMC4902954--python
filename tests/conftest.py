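import pytest

from earlycea import CANDIDATE_TESTS, default_parameters
from earlycea.strategy import StrategyMode, StrategySpec


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def cohort(params):
    return params.cohort


@pytest.fixture(scope="session")
def current_strategy():
    return StrategySpec(StrategyMode.CURRENT)


@pytest.fixture(scope="session")
def bcell_intermediate():
    return StrategySpec(StrategyMode.ADD_ON_INTERMEDIATE, CANDIDATE_TESTS["b_cell"])


@pytest.fixture(scope="session")
def bcell_add_on_all():
    return StrategySpec(StrategyMode.ADD_ON_ALL, CANDIDATE_TESTS["b_cell"])
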