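import numpy as np
import pytest

import ryrspark as rs


@pytest.fixture(scope="session")
def tetramer():
    """Single isolated channel (no inter edges)."""
    return rs.build_oblique(1, 1)


@pytest.fixture(scope="session")
def quad_adjoining():
    return rs.build_adjoining(2, 2)


@pytest.fixture(scope="session")
def quad_oblique():
    return rs.build_oblique(2, 2)


@pytest.fixture(scope="session")
def warm_kernel(tetramer):
    """Trigger numba compilation once so timed tests measure simulation only."""
    rs.first_passage_time(tetramer, rs.RateParams(c0=50.0, nc=1), seed=0)


def random_state(rng: np.random.Generator, n_channels: int) -> rs.ClusterState:
    return rs.ClusterState(rng.choice([-1, 1], size=4 * n_channels))
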