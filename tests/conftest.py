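import pytest

from eabsim import DemographyParams, EconParams, builtin_scenarios


@pytest.fixture(scope="session")
def params():
    return DemographyParams()


@pytest.fixture(scope="session")
def econ():
    return EconParams()


@pytest.fixture(scope="session")
def builtins():
    return builtin_scenarios()


@pytest.fixture(scope="session")
def by_name(builtins):
    return {s.name: s for s in builtins}
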