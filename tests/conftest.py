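import numpy as np
import pandas as pd
import pytest

from somhte.cohort import default_sprint_spec, generate_cohort
from somhte.som import fit_som
from somhte.cohort import FRS_COMPONENTS


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """2,000-participant default-spec cohort shared across read-only tests."""
    return generate_cohort(default_sprint_spec(n=2000, seed=7))


@pytest.fixture(scope="session")
def trained_som(small_cohort):
    return fit_som(small_cohort, FRS_COMPONENTS, rings=5, epochs=30, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
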