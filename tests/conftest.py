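from datetime import datetime, timedelta

import pandas as pd
import pytest

from portaltypes.features import cohort_matrix, profiles_for_cohort
from portaltypes.logio import LogRecord
from portaltypes.sessionize import sessionize_cohort
from portaltypes.synthetic_data import (
    DEFAULT_WINDOW,
    default_archetypes,
    generate_cohort,
)

T0 = datetime(2006, 3, 10, 9, 0)


def at(mins: float) -> datetime:
    """Instant ``mins`` minutes after the reference time."""
    return T0 + timedelta(minutes=mins)


def rec(mins: float, event: str, function: str | None = None, pid: str = "p1") -> LogRecord:
    return LogRecord(pid, at(mins), event, function)


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def small_cohort(archetypes):
    """8 archetypes x 12 patients + 6 non-users: fast, full-pipeline-capable."""
    return generate_cohort(archetypes, 12, DEFAULT_WINDOW, seed=11, n_nonusers=6)


@pytest.fixture(scope="session")
def small_sessions(small_cohort):
    return sessionize_cohort(small_cohort.records, DEFAULT_WINDOW)


@pytest.fixture(scope="session")
def small_matrix(small_sessions) -> pd.DataFrame:
    return cohort_matrix(profiles_for_cohort(small_sessions))


@pytest.fixture(scope="session")
def default_cohort(archetypes):
    """The default study-scale cohort: 8 x 50 active archetypes + 20 non-users."""
    return generate_cohort(archetypes, 50, DEFAULT_WINDOW, seed=1, n_nonusers=20)


@pytest.fixture(scope="session")
def default_matrix(default_cohort) -> pd.DataFrame:
    sess = sessionize_cohort(default_cohort.records, DEFAULT_WINDOW)
    return cohort_matrix(profiles_for_cohort(sess))
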