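import numpy as np
import pandas as pd
import pytest

from eigenlife import BehaviorMatrix, CohortSpec, generate_cohort
from eigenlife.lexicons import ACTIVITY, DIET


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (21 subjects x 10 days), fixed seed."""
    return generate_cohort(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for the slower pipeline-level tests."""
    spec = CohortSpec(n_subjects=10, days_per_subject=8, seed=11)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_behavior_matrix(rng, n_days, category=ACTIVITY, p=0.3):
    from eigenlife.behavior import behavior_columns
    from eigenlife.lexicons import default_lexicon, default_scheme

    cols = behavior_columns(default_lexicon(category), default_scheme(category))
    values = (rng.random((n_days, len(cols))) < p).astype(float)
    return BehaviorMatrix(category=category,
                          row_labels=list(range(1, n_days + 1)),
                          col_labels=cols, values=values)
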