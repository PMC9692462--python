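import pytest

from radaudit import MethodKey, default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def b3lyp_tz():
    return MethodKey("B3LYP", "6-311++G(d,p)")


@pytest.fixture(scope="session")
def b3lyp_dz():
    return MethodKey("B3LYP", "6-31+G(d,p)")
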