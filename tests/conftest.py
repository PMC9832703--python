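import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mpcbio import Session, PartitionCache

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def session():
    return Session(seed=1234)


@pytest.fixture
def session3():
    return Session(n_parties=3, seed=99)


@pytest.fixture
def cache():
    return PartitionCache()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
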