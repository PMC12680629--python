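import numpy as np
import pytest

from iepfit import GammaPriorPair, IEPParams, fit_mle, load_region


@pytest.fixture(scope="session")
def afr():
    return load_region("AFR").sample


@pytest.fixture(scope="session")
def afr_fit(afr):
    return fit_mle(afr)


@pytest.fixture(scope="session")
def default_priors():
    return GammaPriorPair()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def param_grid():
    vals = [0.5, 1.0, 2.0, 4.0]
    return [IEPParams(a, l) for a in vals for l in vals]
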