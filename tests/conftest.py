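import pytest
from hypothesis import HealthCheck, settings

from csurv.synthcohort import SynthConfig, default_blueprints, generate_native_cohort
from csurv.taxonomy import reference_taxonomy, table1_taxonomy

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_tax():
    return reference_taxonomy()


@pytest.fixture(scope="session")
def t1_tax():
    return table1_taxonomy()


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded messy cohort (n=200, default survey battery) + its truth."""
    config = SynthConfig(
        cohort_code="GEN", n_participants=200, variables=default_blueprints(), seed=42
    )
    return generate_native_cohort(config)
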