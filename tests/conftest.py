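import numpy as np
import pytest

from survscreen import SurvivalDataset


@pytest.fixture
def three_events():
    """Times 1,2,3, all events, one covariate — risk sets of size 3, 2, 1."""
    return SurvivalDataset([1.0, 2.0, 3.0], [1, 1, 1], [[0.5], [-0.2], [1.0]])


@pytest.fixture
def random_dataset():
    """10 x 3 continuous dataset with mixed censoring, no tied times."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((10, 3))
    times = rng.exponential(1.0, 10) + 0.01
    events = np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 1])
    return SurvivalDataset(times, events, X)


def make_single_effect(n=100, beta=3.0, p=5, seed=0):
    """Proportional-hazards data with one strong covariate effect."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    eta = beta * X[:, 0]
    T = rng.exponential(1.0, n) / (0.05 * np.exp(eta))
    C = rng.exponential(20.0, n)
    return SurvivalDataset(np.minimum(T, C), (T <= C).astype(int), X)


def make_noise(n=50, p=20, seed=0):
    """Pure-noise survival data (no covariate effects, ~50% censoring)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    T = rng.exponential(20.0, n)
    C = rng.exponential(20.0, n)
    return SurvivalDataset(np.minimum(T, C), (T <= C).astype(int), X)
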