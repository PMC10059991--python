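import numpy as np
import pytest

import glucofed as gf
from glucofed.grammar import glucose_grammar
from glucofed.windows import preprocess_series


@pytest.fixture(scope="session")
def small_cohort_config():
    """Two short synthetic patients: enough structure, fast to build."""
    return gf.CohortConfig(n_patients=2, days=2.0, seed=11)


@pytest.fixture(scope="session")
def patient(small_cohort_config):
    return gf.simulate_patient(small_cohort_config, 0)


@pytest.fixture(scope="session")
def samples(patient):
    return preprocess_series(patient)


@pytest.fixture(scope="session")
def grammar():
    return glucose_grammar()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
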