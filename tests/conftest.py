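import numpy as np
import pytest

from vocrisk.pipeline import process_cohort
from vocrisk.synthetic_data import CohortConfig, generate_cohort

#: Seed fixing the default study cohort used across the suite.
COHORT_SEED = 2021


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic cohort: 212 subjects, ~1:4.9 imbalance."""
    return generate_cohort(CohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def default_dataset(default_bundle):
    """The default cohort run through the full signal-to-feature pipeline."""
    return process_cohort(default_bundle, with_candidate_pool=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
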