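import numpy as np
import pytest

from ifngate import DEFAULT_PARAMS, ModelParameters
from ifngate.synthetic import generate_fitting_dataset


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def noiseless_dataset(default_params):
    """Fitting dataset simulated from the shipped defaults at tau = 8 h,
    no observation noise."""
    return generate_fitting_dataset(default_params, tau=8.0, noise_frac=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
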