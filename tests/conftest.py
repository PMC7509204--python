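import numpy as np
import pytest

import vagalflex as vf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject cohort with default latent structure (fast fixture)."""
    spec = vf.CohortSpec(n_subjects=12, seed=5)
    sessions, truth = vf.generate_cohort(spec)
    return sessions, truth


@pytest.fixture(scope="session")
def cohort47():
    """A study-sized cohort (47 subjects) with its profiles, shared across
    pipeline and inference tests to keep the suite fast."""
    spec = vf.CohortSpec(n_subjects=47, seed=2024)
    sessions, truth = vf.generate_cohort(spec)
    profiles, condition_scores = vf.build_profiles(sessions)
    return sessions, truth, profiles, condition_scores
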