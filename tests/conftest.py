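import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from amytraj import GeneratorConfig, annualize, generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def default_cohort():
    """Default matched-cohort simulation (35 cases, 1000-control pool)."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def pooled_annualized():
    """Annualized changes for a 1000-case cohort spanning the SUVR range."""
    _, visits = generate_cohort(
        GeneratorConfig(seed=1, n_cases=1000, control_pool_size=0)
    )
    return annualize(visits)


@pytest.fixture(scope="session")
def two_group_annualized():
    """Annualized changes for a 200-case / 800-control cohort."""
    _, visits = generate_cohort(
        GeneratorConfig(seed=7, n_cases=200, control_pool_size=800)
    )
    return annualize(visits)


@pytest.fixture()
def rng():
    return np.random.default_rng(20259)
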