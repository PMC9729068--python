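import numpy as np
import pytest

from migsci.params import MSciParams, preset_scenario


@pytest.fixture(scope="session")
def im_params():
    return preset_scenario("fig1-im").mscm


@pytest.fixture(scope="session")
def iim_params():
    return preset_scenario("fig1-iim").mscm


@pytest.fixture(scope="session")
def sc_params():
    return preset_scenario("fig1-sc").mscm


@pytest.fixture(scope="session")
def msci_truth():
    """Two-species MSci truth used for self-simulation checks."""
    return MSciParams(tau_R=0.004, tau_S=0.002, theta_R=0.01, theta_S=0.01, phi=0.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)
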