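import numpy as np
import pytest

from news2l.cohort import CohortSpec, cohort_to_frame, generate_cohort
from news2l.pipeline import score_cohort


@pytest.fixture(scope="session")
def big_cohort_frame():
    """A 10,000-patient synthetic cohort at the default study conditions,
    scored, shared across calibration tests."""
    records = generate_cohort(CohortSpec(n=10_000), seed=20180401)
    return score_cohort(cohort_to_frame(records))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
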