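import dataclasses

import numpy as np
import pytest

from stopbayes import CohortConfig, DBMParams, SubjectProfile, generate_cohort, make_schedule


@pytest.fixture(scope="session")
def default_params() -> DBMParams:
    return DBMParams()


@pytest.fixture(scope="session")
def random_sequences():
    """A handful of seeded 25%-stop go/stop sequences."""
    rng = np.random.default_rng(12345)
    return [(rng.random(400) < 0.25).astype(int) for _ in range(5)]


@pytest.fixture(scope="session")
def stationary_profile() -> SubjectProfile:
    """Subject with no drift and no anticipatory slowing (staircase fixed point)."""
    return SubjectProfile(
        subject_id="stat01",
        gender="M",
        age=30.0,
        ns=4,
        ha=6,
        rd=6,
        slowing_coef_ms=0.0,
        drift_ms_per_100trials=0.0,
    )


@pytest.fixture(scope="session")
def default_profile() -> SubjectProfile:
    return SubjectProfile(subject_id="sub01", gender="F", age=28.0, ns=4, ha=7, rd=6)


@pytest.fixture(scope="session")
def subject_events(default_profile):
    """One simulated 4 x 100-trial subject (generating p(Stop) attached)."""
    from stopbayes import simulate_subject

    sched = make_schedule(400, seed=42, n_sessions=4, session_duration_s=600.0)
    return simulate_subject(default_profile, sched, seed=43)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject cohort with BOLD, shared across tests (deterministic)."""
    cfg = dataclasses.replace(CohortConfig(), n_subjects=12, n_female=7)
    return generate_cohort(cfg, seed=7, include_bold=True)
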