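"""Core domain types and CSV input/output for daily pain-diary cohorts.

The pipeline operates on two tables: a long-format daily diary
(participant id, calendar date, ordinal pain score 1-5) and a
demographics table (sex, age group, multi-label chronic pain conditions,
join/leave dates).  Dates are timezone-free calendar dates throughout;
the analysis is day-granular.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SCORE_MIN = 1
SCORE_MAX = 5

#: Pain severity anchors of the daily question ("How severe was your pain
#: today?"): 1=no pain, 2=mild, 3=moderate, 4=severe, 5=very severe.
SCORE_LABELS = {1: "no pain", 2: "mild", 3: "moderate", 4: "severe", 5: "very severe"}

AGE_GROUPS = ("17-24", "25-34", "35-44", "45-54", "55-64", "65-86")

#: Default chronic pain condition vocabulary (multi-label; a participant
#: may report any subset, including none).
CONDITIONS = (
    "rheumatoid arthritis",
    "osteoarthritis",
    "spondyloarthropathy",
    "gout",
    "unspecific arthritis",
    "fibromyalgia",
    "chronic headache",
    "neuropathic pain",
    "other or no medical diagnosis",
)

SEXES = ("female", "male")


class MissingColumnsError(ValueError):
    """A required CSV column is absent."""


class EmptyFileError(ValueError):
    """The CSV contains a header but no data rows (or nothing at all)."""


class DuplicateParticipantError(ValueError):
    """The demographics table lists the same participant twice."""


@dataclass(frozen=True, slots=True)
class DailyRecord:
    """One participant-day ordinal pain score: the atomic input."""

    participant_id: str
    date: dt.date
    score: int

    def __post_init__(self) -> None:
        if not (SCORE_MIN <= int(self.score) <= SCORE_MAX):
            raise ValueError(
                f"score must be in {SCORE_MIN}..{SCORE_MAX}, got {self.score!r}"
            )


@dataclass(frozen=True, slots=True)
class Participant:
    """Baseline characteristics and study window of one participant."""

    participant_id: str
    sex: str
    age_group: str
    conditions: frozenset = frozenset()
    join_date: dt.date = dt.date.min
    last_date: dt.date = dt.date.max

    def __post_init__(self) -> None:
        if self.join_date > self.last_date:
            raise ValueError(
                f"{self.participant_id}: join_date {self.join_date} after "
                f"last_date {self.last_date}"
            )


@dataclass(frozen=True, slots=True)
class WeekTrajectory:
    """Seven consecutive daily scores aligned to a week start day.

    ``scores[i]`` is the score on ``week_start + i`` days; all seven days
    must be present (the clustering unit is the complete participant week).
    """

    participant_id: str
    week_start: dt.date
    scores: tuple

    def __post_init__(self) -> None:
        if len(self.scores) != 7:
            raise ValueError(f"a week needs exactly 7 scores, got {len(self.scores)}")
        for s in self.scores:
            if not (SCORE_MIN <= int(s) <= SCORE_MAX):
                raise ValueError(f"score out of range: {s!r}")


@dataclass
class Dataset:
    """A diary table plus its demographics table, cross-validated."""

    records: list = field(default_factory=list)
    participants: list = field(default_factory=list)

    def validate(self) -> None:
        by_id = {p.participant_id: p for p in self.participants}
        if len(by_id) != len(self.participants):
            raise DuplicateParticipantError("duplicate participant_id in participants")
        for r in self.records:
            p = by_id.get(r.participant_id)
            if p is None:
                raise ValueError(f"record for unknown participant {r.participant_id!r}")
            if not (p.join_date <= r.date <= p.last_date):
                raise ValueError(
                    f"{r.participant_id}: record on {r.date} outside study window "
                    f"[{p.join_date}, {p.last_date}]"
                )

    def records_frame(self) -> pd.DataFrame:
        """Long-format view of the diary (participant_id, date, score)."""
        return pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in self.records],
                "date": [r.date for r in self.records],
                "score": [r.score for r in self.records],
            }
        )

    def participants_by_id(self) -> Mapping[str, Participant]:
        return {p.participant_id: p for p in self.participants}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnsError(f"{path}: missing columns {missing}")


def _parse_date(value) -> dt.date:
    return dt.date.fromisoformat(str(value).strip())


def read_daily_csv(path) -> list:
    """Read a long-format daily diary CSV into validated :class:`DailyRecord`.

    Rows with a score outside 1-5 or an unparseable date are rejected and
    logged with their (1-based, header-inclusive) row number.  If several
    rows share a (participant_id, date) key, the last row in file order
    wins and a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["participant_id", "date", "score"], path)
    if len(df) == 0:
        raise EmptyFileError(f"{path}: no data rows")

    out: dict = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            date = _parse_date(row.date)
            score = int(row.score)
        except (ValueError, TypeError) as exc:
            logger.warning("%s row %d: rejected (%s)", path, i, exc)
            continue
        if not (SCORE_MIN <= score <= SCORE_MAX):
            logger.warning(
                "%s row %d: rejected (score %r outside %d..%d)",
                path, i, score, SCORE_MIN, SCORE_MAX,
            )
            continue
        key = (str(row.participant_id), date)
        if key in out:
            logger.warning(
                "%s row %d: duplicate (participant_id, date) %s; keeping last", path, i, key
            )
        out[key] = DailyRecord(key[0], date, score)
    return list(out.values())


def read_demographics_csv(path, known_conditions: Iterable[str] = CONDITIONS) -> list:
    """Read the demographics CSV; conditions are semicolon-separated.

    Unknown condition labels are kept but warned about; a duplicated
    participant_id is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        df,
        ["participant_id", "sex", "age_group", "conditions", "join_date", "last_date"],
        path,
    )
    if len(df) == 0:
        raise EmptyFileError(f"{path}: no data rows")

    known = set(known_conditions)
    seen = set()
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(row.participant_id)
        if pid in seen:
            raise DuplicateParticipantError(f"{path} row {i}: duplicate participant_id {pid!r}")
        seen.add(pid)
        conds = frozenset(c.strip() for c in str(row.conditions).split(";") if c.strip())
        for c in conds - known:
            logger.warning("%s row %d: unknown condition label %r", path, i, c)
        out.append(
            Participant(
                participant_id=pid,
                sex=str(row.sex),
                age_group=str(row.age_group),
                conditions=conds,
                join_date=_parse_date(row.join_date),
                last_date=_parse_date(row.last_date),
            )
        )
    return out


def write_daily_csv(records: Iterable[DailyRecord], path) -> None:
    df = pd.DataFrame(
        [(r.participant_id, r.date.isoformat(), r.score) for r in records],
        columns=["participant_id", "date", "score"],
    )
    df.to_csv(path, index=False)


def write_demographics_csv(participants: Iterable[Participant], path) -> None:
    df = pd.DataFrame(
        [
            (
                p.participant_id,
                p.sex,
                p.age_group,
                ";".join(sorted(p.conditions)),
                p.join_date.isoformat(),
                p.last_date.isoformat(),
            )
            for p in participants
        ],
        columns=["participant_id", "sex", "age_group", "conditions", "join_date", "last_date"],
    )
    df.to_csv(path, index=False)


def write_assignments(trajectories: Sequence[WeekTrajectory], labels: Sequence, path) -> None:
    """Write one row per trajectory: participant_id, week_start, cluster_label."""
    if len(trajectories) != len(labels):
        raise ValueError(
            f"{len(trajectories)} trajectories but {len(labels)} labels"
        )
    df = pd.DataFrame(
        [
            (t.participant_id, t.week_start.isoformat(), lab)
            for t, lab in zip(trajectories, labels)
        ],
        columns=["participant_id", "week_start", "cluster_label"],
    )
    df.to_csv(path, index=False)


def read_assignments(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_assignments` output."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "cluster_label": str})
    _require_columns(df, ["participant_id", "week_start", "cluster_label"], path)
    df["week_start"] = df["week_start"].map(_parse_date)
    return df


def write_weeks_csv(trajectories: Sequence[WeekTrajectory], path) -> None:
    """Wide per-week CSV: participant_id, week_start, d1..d7."""
    rows = [
        (t.participant_id, t.week_start.isoformat(), *t.scores) for t in trajectories
    ]
    df = pd.DataFrame(rows, columns=["participant_id", "week_start"] + [f"d{i}" for i in range(1, 8)])
    df.to_csv(path, index=False)


def read_weeks_csv(path) -> list:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ["participant_id", "week_start"] + [f"d{i}" for i in range(1, 8)], path)
    return [
        WeekTrajectory(
            participant_id=str(row.participant_id),
            week_start=_parse_date(row.week_start),
            scores=tuple(int(getattr(row, f"d{i}")) for i in range(1, 8)),
        )
        for row in df.itertuples(index=False)
    ]
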