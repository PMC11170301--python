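import pytest
from hypothesis import HealthCheck, settings

import erpo_avert as ea

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def male_cfr() -> ea.CFRTable:
    return ea.male_cfr_table()


@pytest.fixture(scope="session")
def ct_deaths() -> ea.DeathTally:
    return ea.connecticut_death_tally()


@pytest.fixture(scope="session")
def owner_dist() -> ea.MethodDistribution:
    return ea.owner_male_act_distribution()


@pytest.fixture(scope="session")
def ct_scenario() -> ea.Scenario:
    return ea.connecticut_scenario()


@pytest.fixture
def toy_taxonomy() -> ea.MethodTaxonomy:
    return ea.MethodTaxonomy(("firearm", "hanging", "cutting"))
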