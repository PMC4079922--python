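import numpy as np
import pytest

from vitd_uacr import GeneratorConfig, generate_cohort, generate_exclusion_fixture


@pytest.fixture(scope="session")
def small_cohort():
    """Default-configured cohort, small n, for fast structural tests."""
    return generate_cohort(GeneratorConfig(n_subjects=2_000, seed=1))


@pytest.fixture(scope="session")
def big_cohort():
    """Study-scale cohort with the default change-point link."""
    return generate_cohort(GeneratorConfig(n_subjects=15_000, seed=3))


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 16,870-record exclusion-arithmetic fixture."""
    return generate_exclusion_fixture(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
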