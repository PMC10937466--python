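import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240229)


@pytest.fixture
def noise_free_spec():
    """Default study-condition synapse with noise disabled for exact geometry."""
    from nanocol import SimSpec

    return SimSpec(poisson_noise=False, seed=7)
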