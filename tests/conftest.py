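import warnings

import numpy as np
import pytest

import facedcm as fd
from facedcm.inversion import default_priors, invert
from facedcm.synthetic_data import generate_subject


@pytest.fixture(scope="session")
def model_space():
    return fd.build_model_space()


@pytest.fixture(scope="session")
def m1(model_space):
    return model_space[0]


@pytest.fixture(scope="session")
def m5(model_space):
    return model_space[4]


@pytest.fixture(scope="session")
def reduced_regressors():
    schedule = fd.generate_schedule(2, seed=5)
    return fd.build_regressors(schedule, n_scans=200)


@pytest.fixture(scope="session")
def snr4_subject():
    """One M5 subject at SNR 4 from the reduced profile."""
    cfg = fd.GroupConfig.reduced(1, "M5", master_seed=11, target_snr=4.0)
    return generate_subject(cfg, 0)


@pytest.fixture(scope="session")
def m5_posterior_snr4(m5, snr4_subject):
    """Full M5 inversion of the SNR-4 subject, shared across tests."""
    priors = default_priors(m5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return invert(m5, priors, snr4_subject.bold.bold,
                      snr4_subject.regressors)
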