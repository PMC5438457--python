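import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=100,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from mpssim.config import PopulationConfig, StratumConfig
from mpssim.frame import MnoPlan
from mpssim.population import generate_population


@pytest.fixture
def two_strata_config():
    """Urban/rural population with differential ownership and propensities."""
    return PopulationConfig(
        dimensions=("residence",),
        strata=[
            StratumConfig(levels=("urban",), size=600, ownership=0.9,
                          prevalence=0.2, answer_propensity=0.9,
                          response_propensity=1.0),
            StratumConfig(levels=("rural",), size=400, ownership=0.3,
                          prevalence=0.4, answer_propensity=0.5,
                          response_propensity=1.0),
        ],
        phone_counts={1: 1.0})


@pytest.fixture
def two_strata_population(two_strata_config):
    return generate_population(two_strata_config, seed=7)


@pytest.fixture
def plans():
    return [MnoPlan("017", 5, 0.6), MnoPlan("019", 5, 0.4)]


def saturated_config(size=200, n_strata=2, prevalence=0.5):
    """Everyone owns exactly one phone and always answers and completes."""
    return PopulationConfig(
        dimensions=("group",),
        strata=[StratumConfig(levels=(f"g{i}",), size=size, ownership=1.0,
                              prevalence=prevalence, answer_propensity=1.0,
                              response_propensity=1.0)
                for i in range(n_strata)],
        phone_counts={1: 1.0})
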