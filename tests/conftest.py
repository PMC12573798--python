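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


@pytest.fixture(scope="session")
def apomb_seq():
    from tdfrs import apomyoglobin_sequence

    return apomyoglobin_sequence()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
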