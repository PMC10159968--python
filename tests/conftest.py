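import numpy as np
import pytest

from strokemark import ModelSpec, generate_cohort, make_scenario

FAST_GLM = ModelSpec(learner="glm", cv_repeats=2, seed=7)


@pytest.fixture(scope="session")
def uniform_cohort():
    """Registry cohort with homogeneous reperfusion benefit (0.5/step)."""
    return generate_cohort(make_scenario("uniform_benefit", n=3000, seed=101))


@pytest.fixture(scope="session")
def null_cohort():
    """Registry cohort with no reperfusion benefit anywhere."""
    return generate_cohort(make_scenario("null_benefit", n=3000, seed=102))


@pytest.fixture(scope="session")
def rct_cohort():
    """Two-arm cohort where allocation acts only through reperfusion."""
    return generate_cohort(make_scenario("rct_mediated", n=3000, seed=103))


@pytest.fixture
def fast_glm_spec():
    return FAST_GLM


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
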