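import pytest
from hypothesis import HealthCheck, settings

from skinstretch import ControlConfig, MotorParams, PulseSpec, SkinLoad

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def spec():
    return PulseSpec()


@pytest.fixture
def motors():
    return (MotorParams(), MotorParams())


@pytest.fixture
def skin_load():
    """Skin-like default load: attenuates but preserves timing."""
    return SkinLoad(stiffness=300.0, damping=2.0)


@pytest.fixture
def quiet_control():
    """Noiseless control config for deterministic round-trip checks."""
    return ControlConfig(noise_sd=0.0, seed=1)
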