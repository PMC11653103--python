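import numpy as np
import pytest

import costria
from costria.synthetic import reference_protocol


@pytest.fixture(scope="session")
def protocol():
    return reference_protocol(n_trains=50)


@pytest.fixture(scope="session")
def small_s1_session():
    """Small cortical session shared by read-only tests."""
    return costria.simulate_session(costria.default_config("S1", n_units=40, seed=11))


@pytest.fixture(scope="session")
def small_dlst_session():
    return costria.simulate_session(costria.default_config("DLSt", n_units=40, seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
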