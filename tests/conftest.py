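import numpy as np
import pytest

from gelshell import (
    GelFill,
    MaterialSet,
    ObstacleSet,
    Plane,
    ScenarioConfig,
    SolverOptions,
    build_reference_profile,
    scenario_default_profile,
    solve_equilibrium,
)


@pytest.fixture(scope="session")
def profile200():
    return build_reference_profile(52.87, 45.7, 200_000.0, 64, implant_id="200cc")


@pytest.fixture(scope="session")
def materials():
    return MaterialSet()


@pytest.fixture(scope="session")
def ground():
    return ObstacleSet([Plane(0.0)])


@pytest.fixture(scope="session")
def resting200(profile200, materials, ground):
    """200 cc implant resting flat under gravity (fully filled)."""
    return solve_equilibrium(
        profile200,
        materials,
        GelFill(1.0, 200_000.0),
        ground,
        options=SolverOptions(record_trace=True),
    )


@pytest.fixture(scope="session")
def scenario_config():
    """Light scenario configuration (48-sample meridian) shared by tests."""
    return ScenarioConfig(profile=scenario_default_profile(48))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
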