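import numpy as np
import pytest

from ifegenia.inheritance import GeneticParams, build_cube
from ifegenia.lifecycle import LifeHistoryParams, calibrate


@pytest.fixture(scope="session")
def default_genetics():
    return GeneticParams()


@pytest.fixture(scope="session")
def default_cube(default_genetics):
    return build_cube(default_genetics)


@pytest.fixture(scope="session")
def default_life():
    return LifeHistoryParams()


@pytest.fixture(scope="session")
def default_cal(default_life):
    return calibrate(default_life)


@pytest.fixture(scope="session")
def small_life():
    """Scaled-down population for stochastic property tests."""
    return LifeHistoryParams(N_eq=1000)


@pytest.fixture(scope="session")
def small_cal(small_life):
    return calibrate(small_life)
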