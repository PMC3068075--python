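import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mrse_sim.protocol import ProtocolConfig, Simulation
from mrse_sim.scenario import ScenarioConfig, generate_world


@pytest.fixture(scope="session")
def clean_world():
    """Small noise-free world shared by read-only tests."""
    return generate_world(
        ScenarioConfig(
            n_patients=20, n_hospitals=3, typo_rate=0.0, p_twin_identity=0.0, seed=42
        )
    )


@pytest.fixture()
def clean_sim(clean_world):
    return Simulation(clean_world.hospitals, config=ProtocolConfig(seed=17))
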