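import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hsmodels as h

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return h.make_grid(0.0, 1.0, 8)


@pytest.fixture
def rating_grid():
    return h.make_grid(0.0, 100.0, 101)


def random_state(grid, rng):
    n = grid.n_cells
    return h.normalize(
        h.StateVector(grid, rng.normal(size=n) + 1j * rng.normal(size=n))
    )


def random_unitary(grid, rng):
    n = grid.n_cells
    a = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    q, _ = np.linalg.qr(a)
    return h.OperatorMatrix(grid, q, "unitary")


@pytest.fixture
def random_state_factory():
    return random_state


@pytest.fixture
def random_unitary_factory():
    return random_unitary
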