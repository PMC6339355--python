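import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from operon_doe import demo, design, doe, simulate  # noqa: E402


@pytest.fixture(scope="session")
def library():
    return demo.demo_library(ranked=True)


@pytest.fixture(scope="session")
def space(library):
    return design.build_design_space(library, demo.demo_design_config())


@pytest.fixture(scope="session")
def main_effects_model(space):
    return doe.ModelSpec.main_effects(space)


@pytest.fixture(scope="session")
def design88(space, main_effects_model):
    """The canonical 88-run D-optimal reduction of the 810-config space."""
    return doe.select_d_optimal(space, main_effects_model, 88, seed=17, n_starts=10)


@pytest.fixture(scope="session")
def truth88(space, design88):
    """Default ground truth calibrated against the 88-run design."""
    return simulate.calibrated_truth(space, design88)
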