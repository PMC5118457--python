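import logging
import warnings

import numpy as np
import pytest

from acifit.kinetics import own_kinetics
from acifit.synthetic import default_true_parameters, simulate_c3_curve, simulate_c4_curve

logging.getLogger("acifit").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* points")
        yield


@pytest.fixture(scope="session")
def rice25():
    return own_kinetics("rice", 25.0)


@pytest.fixture(scope="session")
def maize25():
    rub, pepc = own_kinetics("maize", 25.0)
    return rub, pepc


@pytest.fixture(scope="session")
def rice_params():
    return default_true_parameters("rice", 25.0, "WW", 25.0)


@pytest.fixture(scope="session")
def noiseless_c3_curve(rice_params):
    return simulate_c3_curve(rice_params, 25.0, "WW", 25.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def maize_params():
    return default_true_parameters("maize", 25.0, "WW", 25.0)


@pytest.fixture(scope="session")
def noiseless_c4_curve(maize_params):
    return simulate_c4_curve(maize_params, 25.0, "WW", 25.0, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
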