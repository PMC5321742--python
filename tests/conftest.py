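import numpy as np
import pytest

from hexagait.gaits import BIPOD_B, TRIPOD_A, GaitPhaseVector, default_class_table
from hexagait.simulator import (
    BodyModel,
    SimulationCondition,
    SolverParams,
    StepTrajectoryParams,
)


@pytest.fixture(scope="session")
def model() -> BodyModel:
    return BodyModel()


@pytest.fixture(scope="session")
def traj() -> StepTrajectoryParams:
    return StepTrajectoryParams()


@pytest.fixture(scope="session")
def solver() -> SolverParams:
    return SolverParams()


@pytest.fixture(scope="session")
def ground() -> SimulationCondition:
    return SimulationCondition("ground", adhesion_level=0.0)


@pytest.fixture(scope="session")
def wall_up() -> SimulationCondition:
    return SimulationCondition("wall_up", adhesion_level=200.0)


@pytest.fixture(scope="session")
def class_table():
    return default_class_table()


@pytest.fixture
def random_gaits():
    rng = np.random.default_rng(20260927)

    def _make(n: int) -> list[GaitPhaseVector]:
        return [GaitPhaseVector.from_free(rng.uniform(0, 360, 5)) for _ in range(n)]

    return _make


@pytest.fixture(scope="session")
def tripod_a() -> GaitPhaseVector:
    return TRIPOD_A


@pytest.fixture(scope="session")
def bipod_b() -> GaitPhaseVector:
    return BIPOD_B
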