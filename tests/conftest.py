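import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20170370)


def simulate_coupled_pair(rng, T, coupling, ar=0.0):
    """x white-ish AR(1), y driven by x at lag 1: the canonical GC test system."""
    x = np.empty(T)
    y = np.empty(T)
    ex = rng.standard_normal(T)
    ey = rng.standard_normal(T)
    x[0], y[0] = ex[0], ey[0]
    for t in range(1, T):
        x[t] = ar * x[t - 1] + ex[t]
        y[t] = ar * y[t - 1] + coupling * x[t - 1] + ey[t]
    return x, y


@pytest.fixture
def coupled_pair_factory():
    return simulate_coupled_pair
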