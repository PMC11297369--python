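import datetime as dt
import itertools

import numpy as np
import pytest

from paintraj.datamodel import DailyRecord, Dataset, Participant
from paintraj.weeks import (WeekPair, aligned_week_start, consecutive_pairs,
                            extract_complete_weeks, weekday_index)
from .conftest import MONDAY, full_week_records, make_week, simple_dataset


def participant(pid, join, last):
    return Participant(pid, "female", "45-54", frozenset(), join, last)


class TestExtraction:
    def test_three_consecutive_weeks_yield_three_trajectories(self):
        ds = simple_dataset(n_weeks=3)
        weeks = extract_complete_weeks(ds)
        assert len(weeks) == 3
        assert [w.week_start for w in weeks] == [
            MONDAY + dt.timedelta(days=7 * i) for i in range(3)
        ]

    def test_join_after_week_start_excludes_week(self):
        # all 7 days of week W recorded, but the participant joined on Tuesday
        tuesday = MONDAY + dt.timedelta(days=1)
        records = full_week_records("p1", MONDAY, [3] * 7)
        records += full_week_records("p1", MONDAY + dt.timedelta(days=7), [3] * 7)
        ds = Dataset(records=records,
                     participants=[participant("p1", tuesday,
                                               MONDAY + dt.timedelta(days=13))])
        weeks = extract_complete_weeks(ds)
        assert [w.week_start for w in weeks] == [MONDAY + dt.timedelta(days=7)]

    def test_six_of_seven_days_excluded(self):
        records = full_week_records("p1", MONDAY, [3] * 7)[:-1]
        ds = Dataset(records=records,
                     participants=[participant("p1", MONDAY,
                                               MONDAY + dt.timedelta(days=6))])
        assert extract_complete_weeks(ds) == []

    def test_leaving_before_week_end_excludes_week(self):
        # all 7 scores present but last_date is the Saturday
        records = full_week_records("p1", MONDAY, [3] * 7)[:-1]
        ds = Dataset(records=records,
                     participants=[participant("p1", MONDAY,
                                               MONDAY + dt.timedelta(days=5))])
        assert extract_complete_weeks(ds) == []

    def test_week_boundary_aligned_counts(self):
        # missing_day_prob = 0 and window aligned to weeks: floor(days/7) weeks
        for n_weeks in (1, 4, 9):
            ds = simple_dataset(n_weeks=n_weeks)
            assert len(extract_complete_weeks(ds)) == n_weeks

    def test_max_weeks_cap(self):
        ds = simple_dataset(n_weeks=5)
        assert len(extract_complete_weeks(ds, max_weeks_per_participant=2)) == 2

    def test_extracted_weeks_satisfy_rules_for_any_start_day(self, small_cohort):
        _, dataset, _, _ = small_cohort
        windows = {p.participant_id: (p.join_date, p.last_date)
                   for p in dataset.participants}
        days = {(r.participant_id, r.date) for r in dataset.records}
        for wsd in range(7):
            for t in extract_complete_weeks(dataset, week_start_day=wsd):
                assert t.week_start.weekday() == wsd
                join, last = windows[t.participant_id]
                assert join <= t.week_start
                assert last >= t.week_start + dt.timedelta(days=6)
                for off in range(7):
                    assert (t.participant_id,
                            t.week_start + dt.timedelta(days=off)) in days


class TestPairs:
    def test_three_consecutive_weeks_give_two_pairs(self):
        weeks = extract_complete_weeks(simple_dataset(n_weeks=3))
        pairs = consecutive_pairs(weeks)
        assert len(pairs) == 2
        # the middle week appears as both this week and last week
        middle = weeks[1]
        assert pairs[0].this_week == middle and pairs[1].last_week == middle

    def test_gap_week_breaks_adjacency(self):
        weeks = [make_week("p1", MONDAY), make_week("p1", MONDAY + dt.timedelta(days=14))]
        assert consecutive_pairs(weeks) == []

    def test_participants_never_cross_paired(self):
        weeks = [make_week("p1", MONDAY), make_week("p2", MONDAY + dt.timedelta(days=7))]
        assert consecutive_pairs(weeks) == []

    def test_pair_invariants_enforced(self):
        with pytest.raises(ValueError):
            WeekPair("p1", make_week("p1"), make_week("p2", MONDAY + dt.timedelta(days=7)))
        with pytest.raises(ValueError):
            WeekPair("p1", make_week("p1"), make_week("p1", MONDAY + dt.timedelta(days=14)))

    def test_pair_count_matches_run_length_oracle(self):
        """#pairs == sum over maximal runs of (run length - 1), random inputs."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            weeks = []
            expected = 0
            for p in range(rng.integers(1, 6)):
                present = rng.random(12) < 0.5
                offsets = np.flatnonzero(present)
                weeks += [make_week(f"p{p}", MONDAY + dt.timedelta(days=7 * int(o)))
                          for o in offsets]
                # brute-force run-length count
                expected += sum(
                    (len(list(g)) - 1)
                    for _, g in itertools.groupby(
                        enumerate(offsets), key=lambda t: t[1] - t[0])
                )
            assert len(consecutive_pairs(weeks)) == expected


def test_weekday_helpers():
    assert weekday_index("wed") == 2 and weekday_index(6) == 6
    with pytest.raises(ValueError):
        weekday_index("noday")
    assert aligned_week_start(MONDAY + dt.timedelta(days=3), 0) == MONDAY
    assert aligned_week_start(MONDAY, 2) == MONDAY - dt.timedelta(days=5)
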