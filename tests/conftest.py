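import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from mirserca.duplex_thermo import load_default_params
from mirserca.model_io import load_de_fixture, load_site_fixture


@pytest.fixture(scope="session")
def params():
    return load_default_params()


@pytest.fixture(scope="session")
def de_records():
    return load_de_fixture()


@pytest.fixture(scope="session")
def serca2a_sites():
    return load_site_fixture("SERCA2a")


@pytest.fixture(scope="session")
def serca2b_sites():
    return load_site_fixture("SERCA2b")
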