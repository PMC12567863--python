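import numpy as np
import pytest

from sleeprec.cohort import CohortSpec, MissingnessSpec, generate_cohort, generate_population
from sleeprec.recommend import default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """30 users x 28 nights with ratings and injected missingness."""
    spec = CohortSpec(n_users=30, n_nights=28, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def clean_small_cohort(small_cohort):
    from sleeprec.profiles import clean_cohort

    cohort, truth = small_cohort
    clean, removal = clean_cohort(cohort)
    return clean, truth, removal


@pytest.fixture(scope="session")
def pristine_cohort():
    """60 users x 28 nights, no missingness (for statistics-sensitive tests)."""
    spec = CohortSpec(
        n_users=60, n_nights=28, seed=3,
        missingness=MissingnessSpec(gap_rate=0.0, drop_rate=0.0, unknown_rate=0.0),
    )
    return generate_population(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
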