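import logging

import pytest
from hypothesis import HealthCheck, settings

from standgrade import PopulationConfig, generate_trees, preset_moe_model

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

# the preset-model centering warning is informative once, noisy in a suite
logging.getLogger("standgrade.moe_model").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def preset_model():
    return preset_moe_model()


@pytest.fixture(scope="session")
def default_population():
    """The default synthetic survey: 333 trees in 67 plots, seed 0."""
    return generate_trees(PopulationConfig(seed=0))
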