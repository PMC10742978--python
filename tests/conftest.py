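import pytest

from dentage import (
    CohortSpec,
    MaturationModel,
    derive_tables,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def zero_model():
    """Degenerate maturation model: no tempo variation, no mis-staging."""
    return MaturationModel.default(individual_effect_sd=0.0, observation_noise=0.0)


@pytest.fixture(scope="session")
def study_model():
    """Study-emulating model with default variation."""
    return MaturationModel.default()


@pytest.fixture(scope="session")
def tables(zero_model):
    """Reference tables exactly consistent with the generating model."""
    return derive_tables(zero_model)


@pytest.fixture(scope="session")
def zero_cohort(zero_model):
    """324-subject study-composition cohort, deterministic stages."""
    return simulate_cohort(CohortSpec.study_default(), zero_model, seed=11)


@pytest.fixture(scope="session")
def noisy_cohort(study_model):
    return simulate_cohort(CohortSpec.study_default(), study_model, seed=12)
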