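import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rsvpdi import cohort


@pytest.fixture(scope="session")
def default_config():
    return cohort.GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def small_profiles():
    """60 participants under the default calibration; cheap, reused widely."""
    return cohort.gen_profiles(cohort.GeneratorConfig(n_participants=60, seed=42))


@pytest.fixture(scope="session")
def large_profiles():
    """5,000 participants for Monte-Carlo oracle checks."""
    return cohort.gen_profiles(cohort.GeneratorConfig(n_participants=5000, seed=11))


@pytest.fixture(scope="session")
def di_matrix_100x80():
    """Binary intrusion matrix of the default-scale study: 100 x 80, session 1."""
    profs = cohort.gen_profiles(cohort.GeneratorConfig(n_participants=100, seed=5))
    trials = cohort.gen_di_trials(profs, 80, session=1, seed=5)
    mat, pids = cohort.di_trial_matrix(trials)
    return mat


def kr20(matrix: np.ndarray) -> float:
    """Independent KR-20 implementation used as an oracle for Cronbach's alpha.

    KR-20 = k/(k-1) * (1 - sum p_j q_j / sigma_X^2) over binary items j,
    coded directly from the definition with sample variances.
    """
    m = np.asarray(matrix, dtype=float)
    k = m.shape[1]
    p = m.mean(axis=0)
    n = m.shape[0]
    pq_sample = p * (1 - p) * n / (n - 1)  # sample (ddof=1) item variances
    var_total = m.sum(axis=1).var(ddof=1)
    return k / (k - 1) * (1 - pq_sample.sum() / var_total)
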