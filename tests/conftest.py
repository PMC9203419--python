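import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def galaxy_like():
    """A 100-point data set in the Galaxy-velocity regime: four clusters
    of sizes (5, 55, 30, 10) at locations 9.5/20/24.5/33."""
    from mfmix.simulate import GAUSSIAN4, generate
    y, labels = generate(GAUSSIAN4, seed=12345)
    return y, labels
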