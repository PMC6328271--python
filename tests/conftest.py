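import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

from saccmap.geometry import build_test_grid, default_layout, positions_of_interest


@pytest.fixture(scope="session")
def grid():
    return build_test_grid()


@pytest.fixture(scope="session")
def layout():
    return default_layout("right", "up")


@pytest.fixture(scope="session")
def poi(layout):
    return positions_of_interest(layout)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
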