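import datetime as dt

import numpy as np
import pytest

from paintraj.datamodel import DailyRecord, Dataset, Participant, WeekTrajectory
from paintraj.features import encode_weeks
from paintraj.selection import select_k
from paintraj.synth import SyntheticConfig, generate_cohort
from paintraj.weeks import consecutive_pairs, extract_complete_weeks

MONDAY = dt.date(2016, 2, 1)  # a Monday, start of the simulated study span


def make_week(pid="p1", start=MONDAY, scores=(3,) * 7):
    return WeekTrajectory(pid, start, tuple(scores))


def constant_weeks(levels, pid_prefix="p"):
    """One constant-severity week per level entry (handy clustering input)."""
    return [
        make_week(f"{pid_prefix}{i}", MONDAY, (lvl,) * 7)
        for i, lvl in enumerate(levels)
    ]


def full_week_records(pid, start, scores):
    return [DailyRecord(pid, start + dt.timedelta(days=i), s) for i, s in enumerate(scores)]


def simple_dataset(n_weeks=3, pid="p1", start=MONDAY, score=3):
    """One participant with n_weeks consecutive complete Monday weeks."""
    records = []
    for w in range(n_weeks):
        records += full_week_records(pid, start + dt.timedelta(days=7 * w), [score] * 7)
    join = start
    last = start + dt.timedelta(days=7 * n_weeks - 1)
    return Dataset(records=records,
                   participants=[Participant(pid, "female", "45-54", frozenset(), join, last)])


@pytest.fixture(scope="session")
def small_cohort():
    """60-participant synthetic cohort for cheap integration tests."""
    cfg = SyntheticConfig(n_participants=60, seed=11)
    dataset, truth = generate_cohort(cfg)
    weeks = extract_complete_weeks(dataset)
    return cfg, dataset, truth, weeks


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort (500 participants, planted k=4)."""
    cfg = SyntheticConfig(seed=1)
    dataset, truth = generate_cohort(cfg)
    weeks = extract_complete_weeks(dataset)
    pairs = consecutive_pairs(weeks)
    return cfg, dataset, truth, weeks, pairs


@pytest.fixture(scope="session")
def main_selection(default_cohort):
    """Main-analysis k selection (CLARA, Manhattan) on the default cohort."""
    _, _, _, weeks, _ = default_cohort
    X = encode_weeks(weeks, "ordinal7")
    return select_k(X, k_range=(1, 20), method="clara", metric="manhattan",
                    n_runs=20, base_seed=1000)


@pytest.fixture(scope="session")
def transition_cohort():
    """Larger cohort (same generator settings) giving >=5000 consecutive pairs."""
    cfg = SyntheticConfig(n_participants=2000, seed=2)
    dataset, truth = generate_cohort(cfg)
    weeks = extract_complete_weeks(dataset)
    pairs = consecutive_pairs(weeks)
    assert len(pairs) >= 5000
    return cfg, dataset, truth, weeks, pairs
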