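import logging

import pytest
from hypothesis import HealthCheck, settings

import multistress as ms

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def default_config():
    return ms.SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def default_table(default_config):
    table, _ = ms.generate_experiment(default_config)
    return table


@pytest.fixture(scope="session")
def study(default_table):
    """One shared study so expensive curve fits are cached across tests."""
    return ms.MultiStressStudy(default_table)


@pytest.fixture(scope="session")
def capacity():
    return ms.StressCapacityDistribution()


@pytest.fixture(scope="session")
def symmetric_curve():
    """The canonical symmetric LL5 curve: EC50 exactly at the inflection."""
    return ms.LL5Curve(slope_b=2.0, lower_c=0.0, upper_d=1.0,
                       inflection_e=100.0, asymmetry_f=1.0)
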