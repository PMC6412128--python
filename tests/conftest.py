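import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def triplet():
    from okfire.synthetic import standard_triplet

    return standard_triplet()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
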