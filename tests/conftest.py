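import numpy as np
import pytest

import oncodelay as od


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_config():
    return od.CohortConfig(n=5000, seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """A mid-sized seeded cohort shared across read-only tests."""
    return od.generate_cohort(default_config)


@pytest.fixture(scope="session")
def curves():
    return od.default_curves()


@pytest.fixture(scope="session")
def overall_matrix():
    return od.build_matrix(od.default_table())
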