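import numpy as np
import pytest

from mmstage.schema import default_schema
from mmstage.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def complete_cohort(schema):
    """Default-size cohort with no missing values (seed 11)."""
    return generate_cohort(SyntheticConfig(seed=11, missing_rate=0.0), schema)


@pytest.fixture(scope="session")
def small_cohort(schema):
    """Small complete cohort for fast end-to-end checks."""
    return generate_cohort(
        SyntheticConfig(n_patients=120, seed=3, missing_rate=0.0), schema
    )


@pytest.fixture(scope="session")
def missing_cohort(schema):
    """Default cohort with the default 5% MCAR missingness (seed 5)."""
    return generate_cohort(SyntheticConfig(seed=5), schema)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
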