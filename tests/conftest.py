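import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from isodrift.chem import MolecularFormula
from isodrift.simulate import (
    SimulationConfig,
    build_transaminase_system,
    simulate_timecourse,
)


@pytest.fixture(scope="session")
def glutamate():
    return MolecularFormula.parse("C5H9NO4")


@pytest.fixture(scope="session")
def glutathione():
    return MolecularFormula.parse("C10H17N3O6S")


@pytest.fixture(scope="session")
def active_timecourse():
    """Default active-scenario time course, 0-84 hr, shared across tests."""
    cfg = SimulationConfig(scenario="active", seed=0)
    system = build_transaminase_system(cfg)
    return simulate_timecourse(system, np.linspace(0.0, 84.0, 85), step_hr=0.01)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(scenario="active", seed=0)
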