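import numpy as np
import pytest

from speechdcm import model_space as ms
from speechdcm import neural_mass as nm


@pytest.fixture(scope="session")
def leadfield():
    return nm.make_leadfield()


@pytest.fixture(scope="session")
def stim():
    return nm.StimulusSpec()


@pytest.fixture(scope="session")
def true_model():
    """Default synthetic ground truth: bilateral L3b, forward+backward."""
    return ms.find_model("L3b", "L3b", modulation="forward_and_backward")


@pytest.fixture(scope="session")
def all_models():
    return ms.expand_models()


@pytest.fixture(scope="session")
def erp_pair_default(true_model, stim, leadfield):
    """Noiseless two-condition ERP under the default ground truth."""
    params = nm.default_network_params(true_model, b_backward=-0.4, b_intrinsic=-0.2)
    return nm.simulate_erp_pair(true_model, params, stim, leadfield, dt=0.5, T=500.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
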