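import numpy as np
import pytest

from lacswitch import LacRates, build_lac_network


@pytest.fixture(scope="session")
def tmg_rates():
    return LacRates.defaults("TMG")


@pytest.fixture(scope="session")
def iptg_rates():
    return LacRates.defaults("IPTG")


@pytest.fixture(scope="session")
def npf_network(tmg_rates):
    return build_lac_network("NPF", "TMG", tmg_rates)


@pytest.fixture(scope="session")
def pfb_network(tmg_rates):
    return build_lac_network("PFB", "TMG", tmg_rates)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
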