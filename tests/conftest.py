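import numpy as np
import pytest

from neutroshell.composition import mbp_like
from neutroshell.sld import calibrate_matchout_deuteration


@pytest.fixture(scope="session")
def mbp():
    """Average-composition 42.5 kDa protein stand-in."""
    return mbp_like()


@pytest.fixture(scope="session")
def matchout_deuteration(mbp):
    """Non-labile deuteration that matches the protein out in pure D2O."""
    return calibrate_matchout_deuteration(mbp)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160816)
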