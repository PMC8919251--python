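import numpy as np
import pytest

from p53decode.containers import TimeGrid
from p53decode.kinetic_model import sample_at
from p53decode.synthetic import (OSC_P53_SPEC, RISING_P53_SPEC, hourly_p53)


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid()


@pytest.fixture(scope="session")
def p53_osc():
    """Oscillatory p53 input on the hourly simulation grid."""
    return hourly_p53(OSC_P53_SPEC)


@pytest.fixture(scope="session")
def p53_rise():
    """Rising p53 input on the hourly simulation grid."""
    return hourly_p53(RISING_P53_SPEC)


@pytest.fixture(scope="session")
def p53_ref(p53_osc, grid):
    """Oscillatory p53 reference sampled at the observation grid."""
    return sample_at(p53_osc, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
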