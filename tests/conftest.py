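import pytest

from kanoneeds import datasets, default_instrument, generate_cohort


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


@pytest.fixture(scope="session")
def study_cohort():
    """Deterministic cohort reproducing the published per-item attribute counts."""
    return datasets.study_count_cohort()


@pytest.fixture(scope="session")
def sim_cohort():
    """Small noisy simulated cohort with Likert + Kano + demographics."""
    return generate_cohort(datasets.study_sim_config(n_respondents=120, seed=11))
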