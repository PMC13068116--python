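import numpy as np
import pytest

from thermotee import phantom
from thermotee.heat import MaterialSpec


@pytest.fixture(scope="session")
def noiseless_spec():
    return phantom.default_spec(noise_sd_c=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return phantom.generate_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def plain_body_spec():
    """No occluders, no noise: frame should equal truth exactly."""
    return phantom.default_spec(noise_sd_c=0.0, seed=3, blanket=None, tube=None, screen=None)


@pytest.fixture()
def material():
    return MaterialSpec("fleece-blanket", 0.15)


@pytest.fixture(scope="session")
def tiny_training_pairs():
    """Small varied phantom set for fast training tests (48x64)."""
    return [
        (f, tr.mask) for f, tr in phantom.generate_training_set(16, seed=5, shape=(48, 64))
    ]


def assert_frames_equal(a, b):
    np.testing.assert_array_equal(a.temps, b.temps)
    assert a.ambient_c == b.ambient_c
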