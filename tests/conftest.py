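import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from engage import defaults

settings.register_profile(
    "deterministic",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")
from engage.synthetic import GeneratorConfig, gen_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic cohort shared by read-only tests."""
    return gen_dataset(GeneratorConfig(n=150, seed=42))


@pytest.fixture(scope="session")
def engagement_truth():
    """The six-class generative truth (prevalences + response tables)."""
    return (
        defaults.normalized_gamma(defaults.ENGAGEMENT_GAMMA),
        defaults.normalized_rho(defaults.ENGAGEMENT_RHO),
    )


@pytest.fixture(scope="session")
def subgroup_truth():
    return (
        defaults.normalized_gamma(defaults.SUBGROUP_GAMMA),
        defaults.normalized_rho(defaults.SUBGROUP_RHO),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
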