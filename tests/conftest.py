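import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def exp1_small():
    """The 4-layout direct/indirect design (640 shots per participant)."""
    from spatialpoint import designs

    return designs.exp1(n_layouts=4, seed=0)


@pytest.fixture(scope="session")
def exp4_preset():
    from spatialpoint import designs

    return designs.exp4(seed=0)


@pytest.fixture(scope="session")
def noise8():
    from spatialpoint.noise import NoiseSpec

    return NoiseSpec(sd_deg=8.0)
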