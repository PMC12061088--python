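import pytest
from hypothesis import HealthCheck, settings

from mmepi.codes import CodeListConfig
from mmepi.simulate import SimulationConfig, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def codelists():
    return CodeListConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A modest default-conditions simulation shared across tests."""
    cfg = SimulationConfig(n_persons=5000, seed=11)
    ds, truth = simulate(cfg)
    return ds, truth, cfg


@pytest.fixture(scope="session")
def adversarial_sim():
    """Boundary-case battery plus densified organic patients."""
    cfg = SimulationConfig(n_persons=2000, seed=7, adversarial=True)
    ds, truth = simulate(cfg)
    return ds, truth, cfg


@pytest.fixture(scope="session")
def big_sim():
    """The reference study-scale simulation (200,000 persons)."""
    cfg = SimulationConfig(n_persons=200_000, seed=101)
    ds, truth = simulate(cfg)
    return ds, truth, cfg
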