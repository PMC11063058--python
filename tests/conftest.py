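import pytest
from hypothesis import HealthCheck, settings

from oncoextract import CorpusConfig, MockLLMBackend, generate_cohort
from oncoextract.batch import run_batch

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def clean_config(**overrides) -> CorpusConfig:
    """A cohort config with no irregular reports and no missing sizes, so
    every report is valid and every reference label is determinate."""
    defaults = dict(n_reports=150, seed=20240, irregular_fractions={}, p_size_missing=0.0)
    defaults.update(overrides)
    return CorpusConfig(**defaults)


@pytest.fixture(scope="session")
def clean_cohort():
    return generate_cohort(clean_config())


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort under default study conditions, irregular classes included."""
    return generate_cohort(CorpusConfig(n_reports=200, seed=77))


@pytest.fixture(scope="session")
def clean_records(clean_cohort):
    return run_batch(clean_cohort, MockLLMBackend(), seed=5).records
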