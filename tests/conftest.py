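import pytest

from porospr.physics import BeamSpec, PhysicsConstants


@pytest.fixture(scope="session")
def beam():
    """Carbon-ion beam at 131.0 MeV/u (beta = 0.481) with a water range for pullbacks."""
    return BeamSpec.from_energy(131.0, water_range=155.0)


@pytest.fixture(scope="session")
def constants():
    return PhysicsConstants()


@pytest.fixture(scope="session")
def noiseless_sigmas():
    return {"80kV": 0.0, "120kV": 0.0, "135kV": 0.0}
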