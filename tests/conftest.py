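import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phstat.plant import (reference_calibration, reference_geometry,
                          reference_style)

settings.register_profile(
    "default", derandomize=True, max_examples=100,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture
def geometry():
    return reference_geometry()


@pytest.fixture
def style():
    return reference_style()


@pytest.fixture
def calibration():
    return reference_calibration()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
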