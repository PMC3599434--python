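import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-record synthetic cohort with ceiling censoring (session-wide)."""
    from eq5dmap import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig(n=300, seed=11, mode="latent_censored"))


@pytest.fixture(scope="session")
def small_design(small_cohort):
    from eq5dmap.coding import design_matrix

    X, y, _ = design_matrix(small_cohort)
    return X, y
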