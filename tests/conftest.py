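import numpy as np
import pytest

from emres.environments import get_environment, generate_trajectory
from emres.evolution import EvaluationContext, SearchSpace
from emres.topologies import random_symmetric_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lorenz():
    return get_environment("lorenz")


@pytest.fixture(scope="session")
def small_base():
    """Tiny 20-node base network for fast reservoir tests."""
    return random_symmetric_network(20, np.random.default_rng(99))


@pytest.fixture(scope="session")
def full_base():
    """Standard 100-node uniform random symmetric base network."""
    return random_symmetric_network(100, np.random.default_rng(99))


@pytest.fixture(scope="session")
def tiny_space():
    """Coarse grids for fast GA tests (same genes, fewer values)."""
    return SearchSpace(
        grids={
            "alpha": np.array([0.5, 0.9, 1.3]),
            "beta": np.array([1e-8, 5e-8, 1e-7]),
            "rho": np.array([0.05, 0.10, 0.15]),
            "sigma": np.array([0.03, 0.05, 0.08]),
            "theta": np.array([0.3, 0.5, 0.9]),
        }
    )


@pytest.fixture(scope="session")
def tiny_context(lorenz, small_base):
    """Short-horizon evaluation context on the tiny network.

    Forecast window of 120 steps is the shortest that still supports psi
    estimation (>= 101 steps at lag 1).
    """
    gen = np.random.default_rng(7)
    train = generate_trajectory(lorenz, 400, gen)
    tests = [generate_trajectory(lorenz, 170, gen) for _ in range(3)]
    return EvaluationContext(
        base=small_base, train=train, tests=tests, spin_up=50, forecast_len=120
    )
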