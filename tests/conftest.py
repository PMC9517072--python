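import pytest

from riskperc import MemoryProfile, constant_schedule, covid_fixture


@pytest.fixture
def centre_profile():
    """The study's reference individual: medium memory, general association."""
    return MemoryProfile(rho=0.5, k=0.3)


@pytest.fixture
def baseline_schedule():
    """Constant ten items per period at stimulus two, twenty periods."""
    return constant_schedule(10.0, 2.0, 20)


@pytest.fixture(scope="session")
def t1_schedule():
    return covid_fixture("T1")
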