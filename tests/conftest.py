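import numpy as np
import pytest

from swtime import Design, TreatmentStructure, VarianceComponents
from swtime.simulate import (
    REFERENCE_EFFECTS,
    REFERENCE_VC,
    SimulationScenario,
    reference_scenario,
)


@pytest.fixture(scope="session")
def design_3x4() -> Design:
    """Smallest standard complete design: 3 sequences, 4 periods."""
    return Design(I=3, J=4, K=10)


@pytest.fixture(scope="session")
def ref_design() -> Design:
    """The reference study layout: 18 clusters, 10 periods, 30 per cell."""
    return Design(I=18, J=10, K=30)


@pytest.fixture(scope="session")
def ref_vc() -> VarianceComponents:
    return REFERENCE_VC


@pytest.fixture(scope="session")
def eti_curve() -> TreatmentStructure:
    """Delayed ramp-up exposure-time effect curve (ETATE 2.83...)."""
    return TreatmentStructure("ETI", REFERENCE_EFFECTS["ETI"])


@pytest.fixture(scope="session")
def cti_curve() -> TreatmentStructure:
    """Decaying calendar-time effect curve (CTATE 1.325)."""
    return TreatmentStructure("CTI", REFERENCE_EFFECTS["CTI"])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_scenario() -> SimulationScenario:
    """Cheap scenario for smoke runs: 6 clusters, 4 periods, 4 per cell."""
    return SimulationScenario(
        design=Design(I=6, J=4, K=4),
        structure=TreatmentStructure("IT", [2.0]),
        vc=VarianceComponents(0.1, 0.02, 1.0),
        trend=np.array([1.0, 1.5, 2.0, 2.5]),
        n_reps=10,
        seed=42,
    )


@pytest.fixture(scope="session")
def scenario_factory():
    return reference_scenario
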