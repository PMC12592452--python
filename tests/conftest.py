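import warnings

import pytest
from hypothesis import HealthCheck, settings

from midmix.synthetic import StudyConfig, generate_study

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture(scope="session")
def config():
    return StudyConfig(seed=101)


@pytest.fixture(scope="session")
def study(config):
    return generate_study(config)


@pytest.fixture(scope="session")
def noise_free_study():
    """Consumers planted exactly at their mixture expectations."""
    return generate_study(StudyConfig(seed=101, mis_specified_noise_scale=0.0))
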