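import numpy as np
import pytest

from gtpasekin import cycle_parameters, load_printed_rates


@pytest.fixture(scope="session")
def printed_rates():
    return load_printed_rates()


@pytest.fixture(scope="session")
def wt_params():
    """Published wild-type rate constants assembled into cycle parameters."""
    return cycle_parameters("WT")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
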