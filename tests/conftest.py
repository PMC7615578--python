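import numpy as np
import pytest

from microtract import SMParams, make_default_protocol


@pytest.fixture(scope="session")
def scheme():
    """The five-shell study protocol (254 volumes), fixed seed."""
    return make_default_protocol(seed=1)


@pytest.fixture(scope="session")
def baseline_params():
    """Healthy deep-white-matter Standard Model baseline."""
    return SMParams(f=0.6, d_c=2.2, de_par=2.0, de_perp=0.7, kappa=16.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
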