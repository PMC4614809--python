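import pytest

from hipmoment import (
    HipJoint,
    Posture,
    SweepProtocol,
    SynthSpec,
    ToySpec,
    make_hinge_toy,
    make_hip_model,
)


@pytest.fixture(scope="session")
def default_joint():
    return HipJoint(center=(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def fe_toy():
    """Unit two-link hinge toy for the flexion-extension axis (a = b = 1)."""
    return make_hinge_toy(ToySpec(a=1.0, b=1.0, dof="FE"))


@pytest.fixture(scope="session")
def hip_model():
    """The canonical seeded random hip model (full 19-muscle set)."""
    return make_hip_model(SynthSpec(seed=0))


@pytest.fixture(scope="session")
def small_hip_model():
    return make_hip_model(SynthSpec(seed=1, n_muscles=4))


@pytest.fixture(scope="session")
def default_protocol():
    return SweepProtocol()


@pytest.fixture
def neutral():
    return Posture.neutral()
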