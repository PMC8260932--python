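import pytest

import lipidmr as lm
from lipidmr.simulate import default_scenarios, simulate_cohort


def phenotyped(params) -> lm.AnalyticCohort:
    return lm.apply_exclusions(lm.phenotype_cohort(simulate_cohort(params)))


@pytest.fixture(scope="session")
def effect_cohort() -> lm.AnalyticCohort:
    """Valid-instrument cohort with a causal dementia effect (n=8,000)."""
    return phenotyped(default_scenarios(n=8_000, seed=11)["valid_iv_effect"])


@pytest.fixture(scope="session")
def null_cohort() -> lm.AnalyticCohort:
    """Valid-instrument cohort with no causal effect (n=8,000)."""
    return phenotyped(default_scenarios(n=8_000, seed=13)["valid_iv_null"])


@pytest.fixture(scope="session")
def pleiotropic_cohort() -> lm.AnalyticCohort:
    """Cohort whose instrument has a direct outcome path (n=8,000)."""
    return phenotyped(default_scenarios(n=8_000, seed=17)["pleiotropic"])
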