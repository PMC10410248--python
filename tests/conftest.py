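import warnings

import numpy as np
import pandas as pd
import pytest

import osagut
from osagut import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared across unit tests."""
    cfg = CohortConfig(
        n_participants=500,
        n_species=120,
        n_ko=400,
        n_gmm=12,
        n_true_pos=8,
        n_true_neg=8,
        n_confounded=5,
        seed=42,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """The default study-condition cohort (n=2000, 300 species, effect 0.5)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
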