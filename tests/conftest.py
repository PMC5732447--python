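import numpy as np
import pytest

from hepamri.phantom import default_layout
from hepamri.schemes import (
    default_dti_scheme,
    default_echo_scheme,
    default_ivim_scheme,
)


@pytest.fixture(scope="session")
def ivim_scheme():
    return default_ivim_scheme()


@pytest.fixture(scope="session")
def dti_scheme():
    return default_dti_scheme()


@pytest.fixture(scope="session")
def echo_scheme():
    return default_echo_scheme()


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture()
def rng():
    return np.random.default_rng(20251002)
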