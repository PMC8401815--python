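import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import passivemotion as pm

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def water20() -> pm.FluidMedium:
    """Water at 20 degC with the reference viscosity/density used in the
    closed-form checks."""
    return pm.FluidMedium(temperature=293.15, viscosity=1.002e-3,
                          density=998.0)


@pytest.fixture(scope="session")
def earth(water20) -> pm.MissionEnvironment:
    return pm.MissionEnvironment("Earth", 9.81, water20)


@pytest.fixture(scope="session")
def library() -> pm.MaterialLibrary:
    return pm.MaterialLibrary.default()


@pytest.fixture(scope="session")
def environments(water20):
    return pm.load_environments(water20)
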