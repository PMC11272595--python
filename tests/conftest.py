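import numpy as np
import pytest

from circlequest.geometry import SearchSpace


@pytest.fixture
def small_space() -> SearchSpace:
    """100x100 space with a step-1 grid: dense enough for brute-force oracles."""
    return SearchSpace(width=100, height=100, circle_radius=10, grid_step=1)


@pytest.fixture
def default_space() -> SearchSpace:
    return SearchSpace()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
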