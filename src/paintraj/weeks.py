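"""Complete-participant-week extraction and consecutive-week pairing.

A complete participant week is seven consecutive daily scores from one
participant over an aligned calendar week.  A week is included only if
(1) the participant joined on or before the week start, (2) remained in
the study on or after the week end (operationalised as their final record
date), and (3) provided a score on each of the seven days.  The week
start day is configurable (Monday by default; the day-of-week sensitivity
analysis iterates all seven).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import List, Optional, Sequence

import pandas as pd

from .datamodel import Dataset, WeekTrajectory

WEEKDAY_NAMES = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")


def weekday_index(day) -> int:
    """Normalise a weekday given as 0-6 (Monday=0) or a name like 'wed'."""
    if isinstance(day, str):
        try:
            return WEEKDAY_NAMES.index(day.lower()[:3])
        except ValueError:
            raise ValueError(f"unknown weekday {day!r}; use one of {WEEKDAY_NAMES}")
    day = int(day)
    if not 0 <= day <= 6:
        raise ValueError("weekday index must be 0..6 (Monday=0)")
    return day


def aligned_week_start(date: dt.date, week_start_day: int) -> dt.date:
    """Start of the aligned week containing ``date``."""
    return date - dt.timedelta(days=(date.weekday() - week_start_day) % 7)


@dataclass(frozen=True)
class WeekPair:
    """Two complete weeks of one participant exactly seven days apart."""

    participant_id: str
    last_week: WeekTrajectory
    this_week: WeekTrajectory

    def __post_init__(self) -> None:
        if self.last_week.participant_id != self.this_week.participant_id:
            raise ValueError("paired weeks must belong to the same participant")
        if (self.this_week.week_start - self.last_week.week_start).days != 7:
            raise ValueError("paired weeks must be exactly 7 days apart")


def extract_complete_weeks(dataset: Dataset, week_start_day=0,
                           max_weeks_per_participant: Optional[int] = None
                           ) -> List[WeekTrajectory]:
    """All complete participant weeks of a dataset, sorted by id then date.

    ``max_weeks_per_participant`` optionally truncates each participant's
    (chronologically first) weeks; the study-length cap of the source data
    emerges from the configured span and is not enforced here.
    """
    wsd = weekday_index(week_start_day)
    df = dataset.records_frame()
    if len(df) == 0:
        return []
    windows = {
        p.participant_id: (p.join_date, p.last_date) for p in dataset.participants
    }

    df = df.copy()
    df["week_start"] = df["date"].map(lambda d: aligned_week_start(d, wsd))
    out: List[WeekTrajectory] = []
    for (pid, week_start), grp in df.groupby(["participant_id", "week_start"], sort=True):
        if len(grp) != 7:
            continue  # rule 3: one score on each of the 7 days
        join, last = windows[pid]
        if join > week_start:
            continue  # rule 1: joined on or before the week start
        if last < week_start + dt.timedelta(days=6):
            continue  # rule 2: remained in the study through the week end
        grp = grp.sort_values("date")
        offsets = [(d - week_start).days for d in grp["date"]]
        if offsets != list(range(7)):
            continue  # duplicated/misaligned days cannot form a week
        out.append(
            WeekTrajectory(
                participant_id=pid,
                week_start=week_start,
                scores=tuple(int(s) for s in grp["score"]),
            )
        )
    if max_weeks_per_participant is not None:
        trimmed: List[WeekTrajectory] = []
        count: dict = {}
        for t in out:
            c = count.get(t.participant_id, 0)
            if c < max_weeks_per_participant:
                trimmed.append(t)
                count[t.participant_id] = c + 1
        out = trimmed
    return out


def consecutive_pairs(trajectories: Sequence[WeekTrajectory]) -> List[WeekPair]:
    """All (last week, this week) pairs of adjacent complete weeks.

    A week flanked by complete weeks on both sides appears in two pairs,
    once as *this week* and once as *last week*.
    """
    by_pid: dict = {}
    for t in trajectories:
        by_pid.setdefault(t.participant_id, []).append(t)
    pairs: List[WeekPair] = []
    for pid in sorted(by_pid):
        weeks = sorted(by_pid[pid], key=lambda t: t.week_start)
        for a, b in zip(weeks, weeks[1:]):
            if (b.week_start - a.week_start).days == 7:
                pairs.append(WeekPair(pid, a, b))
    return pairs
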