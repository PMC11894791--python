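import numpy as np
import pytest

from erpmem.layout import SensorLayout, hemisphere_layout


@pytest.fixture(scope="session")
def small_layout() -> SensorLayout:
    """32-sensor hemispheric layout shared across tests."""
    return hemisphere_layout(32)


@pytest.fixture(scope="session")
def full_layout() -> SensorLayout:
    """The packaged 129-sensor layout."""
    return hemisphere_layout(129)


def line_layout(n: int) -> SensorLayout:
    """n sensors on a line with chain adjacency (ids 1..n)."""
    positions = np.column_stack([np.linspace(-1, 1, n), np.zeros(n), np.zeros(n)])
    edges = {(i, i + 1) for i in range(n - 1)}
    return SensorLayout(ids=list(range(1, n + 1)), positions=positions, edges=edges)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
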