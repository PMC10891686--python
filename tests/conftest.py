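import numpy as np
import pytest

from ringtomo.acoustics import make_pulse, make_ring


@pytest.fixture(scope="session")
def ring64():
    return make_ring(64, 200.0, 3.0e6)

@pytest.fixture(scope="session")
def ring8():
    return make_ring(8, 200.0, 3.0e6)


@pytest.fixture(scope="session")
def pulse3mhz():
    return make_pulse(3.0e6, 5, 24.0e6)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240130)
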