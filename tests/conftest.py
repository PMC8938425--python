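import numpy as np
import pytest
from hypothesis import settings

from rnaexcite import (
    ExchangeParams,
    RelaxationRates,
    SpinLockSetting,
    SpinProbe,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def t1_params():
    """Exchange parameters of the prototype hairpin (pES 6.2%, kex 453)."""
    return ExchangeParams.from_populations(0.062, 453.0)


@pytest.fixture
def probe_15n():
    """An imino 15N probe at 60.8 MHz with a 2 ppm downfield ES shift."""
    return SpinProbe.from_ppm(14, "N1", 60.8, gs_ppm=0.0, delta_omega_ppm=2.0)


@pytest.fixture
def rates():
    return RelaxationRates(R1=2.0, R2=18.0)


@pytest.fixture
def delays():
    return np.linspace(0.0, 0.07, 8)


@pytest.fixture
def sl_150():
    return SpinLockSetting.from_hz(150.0, 200.0)
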