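import numpy as np
import pytest
from hypothesis import settings

from judgebias.model import ModelSpec
from judgebias.recovery import default_truth_prior
from judgebias.synth import (
    CohortConfig,
    DesignConfig,
    generate_session1_design,
    generate_session3_design,
    sample_cohort,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def s1_design():
    return generate_session1_design(seed=101)


@pytest.fixture(scope="session")
def s3_design():
    return generate_session3_design(seed=202)


@pytest.fixture(scope="session")
def s1_cohort():
    """Twelve simulated subjects on the fixed-stakes design, 2-param truth."""
    spec = ModelSpec.session1()
    config = CohortConfig(
        n_subjects_per_group=12,
        group_priors={"g": default_truth_prior(spec)},
        spec=spec,
        design=DesignConfig(session="S1", seed=7),
        seed=8,
    )
    cohort, truth = sample_cohort(config)
    return cohort["g"], truth, spec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
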