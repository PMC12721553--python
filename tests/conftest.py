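import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_state(N, rng):
    """Grow a random rank-N ordinal state by uniform edge choices."""
    from phyloar.treespace import TaxaOrder, attach_leaf, init_state

    state = init_state(TaxaOrder.generic(N))
    for n in range(3, N):
        state = attach_leaf(state, int(rng.integers(2 * n - 3)))
    return state
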