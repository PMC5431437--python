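import pytest
from hypothesis import settings

from formulanet.core_data import default_whitelist, load_fixture

settings.register_profile("default", derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def whitelist():
    return default_whitelist()
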