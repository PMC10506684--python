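import pytest

from sectornorm import CohortConfig, assign_strata, generate_cohort
from sectornorm.config import DEFAULT_OUTCOME_MODELS


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort (200 participants, three outcomes) for fast fits."""
    keep = ("nflt_global", "nflt_tl", "gcct_global")
    return CohortConfig(
        n_participants=200,
        outcome_models={k: DEFAULT_OUTCOME_MODELS[k] for k in keep},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return assign_strata(generate_cohort(small_config))


@pytest.fixture(scope="session")
def default_cohort():
    """One default-calibration cohort (~789 participants / ~1339 eyes)."""
    return assign_strata(generate_cohort(seed=0))
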