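import pytest

from cdefair import CohortConfig, generate_cohort, load_catalog, load_term_closures


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def closures():
    return load_term_closures()


@pytest.fixture(scope="session")
def cohort(catalog):
    """A small all-model cohort (one row per patient per model)."""
    return generate_cohort(CohortConfig(n_patients=20, seed=1), catalog)
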