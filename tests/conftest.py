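import numpy as np
import pytest

from repfam.genome import from_records
from repfam.pwm import PWM, PWMConfig, background_p1


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_p1():
    return background_p1(np.full(4, 0.25))


@pytest.fixture
def tiny_genome():
    """Two records of lengths 10 and 5."""
    return from_records([("chr1", "ACGTACGTAC"), ("chr2", "TTGCA")])


@pytest.fixture
def toy_pwm(rng, uniform_p1):
    """Small random profile, 4 columns."""
    w = rng.normal(0.0, 1.0, size=(16, 4))
    return PWM(weights=w, p1=uniform_p1)


@pytest.fixture
def desk_config():
    return PWMConfig.desk()
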