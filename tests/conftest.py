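import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from veilcare.model import InformationState, Mode, make_dyad
from veilcare.simulate import simulate_study

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def veil0():
    return InformationState(Mode.VEIL, 0.0)


@pytest.fixture
def point_a():
    """Smaller asymmetries: zone of disagreement."""
    return make_dyad(1.25, 0.75, 0.25, 0.15)


@pytest.fixture
def point_b():
    """Larger asymmetries: zone of agreement."""
    return make_dyad(1.5, 0.5, 0.3, 0.1)


@pytest.fixture(scope="session")
def default_study():
    """One default-configuration synthetic study, shared across tests."""
    return simulate_study(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
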