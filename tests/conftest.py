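import pytest
from hypothesis import HealthCheck, settings

from circoord.synthetic import KinematicScenario, generate_trial

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_scenario() -> KinematicScenario:
    """Study-shaped scenario with noise and subject variation switched off."""
    return KinematicScenario(noise_rms=0.0, subject_spread_deg=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_scenario):
    return generate_trial(noiseless_scenario, 0, "P1", 1)
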