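import numpy as np
import pandas as pd
import pytest

import hawkdove as hd
from hawkdove.simulate import DEFAULT_SCHEDULE


@pytest.fixture(scope="session")
def schedule():
    return np.array(DEFAULT_SCHEDULE)


@pytest.fixture(scope="session")
def toy_traits():
    """Five-individual cohort for brute-force network checks."""
    return pd.Series({"a": 10.0, "b": 8.1, "c": 6.2, "d": 3.8, "e": 2.0})


@pytest.fixture(scope="session")
def small_cohort():
    return hd.generate_cohort(hd.CohortSpec(n=20, seed=11))


@pytest.fixture(scope="session")
def coupled_cohort():
    """Graded-positive-coupling co-culture cohort (session-cached: growth
    fits are the slow part)."""
    abund, truth = hd.generate_coculture(hd.CocultureSpec(n_pairs=12, seed=21))
    return abund, truth
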