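import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    from icecohort.simulate import fixture_small

    return fixture_small()


@pytest.fixture(scope="session")
def default_config():
    from icecohort.simulate import CohortConfig

    return CohortConfig()


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Mid-sized generated cohort shared across tests (seed fixed)."""
    from icecohort.simulate import CohortConfig, generate

    return generate(CohortConfig(n_population=30_000, seed=42))
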