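import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_posterior(rng, n, k):
    """Random valid responsibility matrix via a Dirichlet draw."""
    return rng.dirichlet(np.ones(k), size=n)


def random_partition(rng, k, n_upper):
    """Random row-stochastic K x L partition."""
    return rng.dirichlet(np.ones(n_upper), size=k)
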