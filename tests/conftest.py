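import numpy as np
import pytest

from glidesphere.geometry import SphereGeometry


@pytest.fixture
def unit_sphere():
    return SphereGeometry(np.zeros(3), 1.0)


@pytest.fixture
def vesicle():
    """An 18 um vesicle at the origin — the nominal experimental scale."""
    return SphereGeometry(np.zeros(3), 18.0)


@pytest.fixture
def offset_vesicle():
    return SphereGeometry(np.array([1.0, -2.0, 0.5]), 18.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
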