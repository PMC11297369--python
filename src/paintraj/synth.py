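"""Synthetic daily-diary cohort generator with planted weekly states.

The generator emulates the structure of a population-based mHealth pain
diary: participants join at staggered dates over a ~15-month span, stay
for a geometric number of weeks, and report a 1-5 ordinal pain score on
each present day (days go missing independently).  Underneath sits a
latent weekly severity-state process: each participant's state is
constant within a Monday-aligned calendar week and moves week-to-week by
a planted row-stochastic transition matrix.  Daily scores are noisy
ordinal emissions around the state's severity anchor (probability
``emission_stay_prob`` on the anchor, the remainder split symmetrically
onto anchor+-1, clipped to the 1..5 scale and renormalised).

Ground-truth states are returned alongside the data so downstream
clustering and transition estimation can be scored as parameter-recovery
problems.  All generator choices are configuration, not claims about the
source study.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import (AGE_GROUPS, CONDITIONS, DailyRecord, Dataset,
                        Participant, SCORE_MAX, SCORE_MIN)
from .weeks import aligned_week_start

#: Week-to-week latent transition default: strong diagonal (~0.66 mean
#: stay) with most off-diagonal mass on adjacent severity states.
DEFAULT_TRANSITION = np.array(
    [
        [0.65, 0.25, 0.07, 0.03],
        [0.15, 0.65, 0.15, 0.05],
        [0.05, 0.15, 0.65, 0.15],
        [0.03, 0.07, 0.25, 0.65],
    ]
)

DEFAULT_INITIAL = np.array([0.08, 0.38, 0.38, 0.16])

#: Baseline demographic marginals (sex, age group, multi-label condition
#: prevalences) for the simulated cohort.
DEFAULT_SEX_PROBS = {"female": 0.8311, "male": 0.1689}
DEFAULT_AGE_PROBS = dict(
    zip(AGE_GROUPS, (0.0239, 0.0908, 0.1810, 0.2690, 0.2807, 0.1546))
)
DEFAULT_CONDITION_PROBS = dict(
    zip(
        CONDITIONS,
        (0.1952, 0.3473, 0.0905, 0.0342, 0.3662, 0.2558, 0.0976, 0.1521, 0.238),
    )
)
#: Log-linear tilt of the initial-state distribution toward the highest
#: (positive) or lowest (negative) severity state for carriers of a label.
DEFAULT_CONDITION_AFFINITY = {
    "fibromyalgia": 1.5,
    "neuropathic pain": 1.5,
    "rheumatoid arthritis": -0.5,
}


@dataclass
class SyntheticConfig:
    """All knobs of the cohort generator; defaults are the study conditions."""

    n_participants: int = 500
    study_start: dt.date = dt.date(2016, 2, 1)  # a Monday
    n_weeks_span: int = 64
    k_true: int = 4
    state_levels: Tuple[int, ...] = (1, 2, 3, 4)
    emission_stay_prob: float = 0.8
    true_transition: Optional[np.ndarray] = None
    initial_state_probs: Optional[np.ndarray] = None
    missing_day_prob: float = 0.1
    mean_duration_weeks: float = 26.0
    sex_probs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    age_group_probs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_PROBS))
    condition_probs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONDITION_PROBS))
    condition_affinity: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONDITION_AFFINITY))
    seed: int = 0

    @property
    def study_end(self) -> dt.date:
        return self.study_start + dt.timedelta(days=7 * self.n_weeks_span - 1)

    def resolved_transition(self) -> np.ndarray:
        T = self.true_transition
        if T is None:
            if self.k_true != 4:
                raise ValueError("true_transition must be given when k_true != 4")
            T = DEFAULT_TRANSITION
        return np.asarray(T, dtype=float)

    def resolved_initial(self) -> np.ndarray:
        p = self.initial_state_probs
        if p is None:
            if self.k_true != 4:
                raise ValueError("initial_state_probs must be given when k_true != 4")
            p = DEFAULT_INITIAL
        return np.asarray(p, dtype=float)

    def validate(self) -> None:
        k = self.k_true
        T = self.resolved_transition()
        p0 = self.resolved_initial()
        if T.shape != (k, k):
            raise ValueError(f"true_transition must be {k}x{k}")
        if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("true_transition rows must be nonnegative and sum to 1")
        if p0.shape != (k,) or np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0, atol=1e-8):
            raise ValueError("initial_state_probs must be a length-k simplex")
        levels = np.asarray(self.state_levels)
        if len(levels) != k or np.any(np.diff(levels) <= 0):
            raise ValueError("state_levels must be strictly increasing, one per state")
        if np.any(levels < SCORE_MIN) or np.any(levels > SCORE_MAX):
            raise ValueError("state_levels must lie on the 1..5 scale")
        if not 0.0 <= self.missing_day_prob < 1.0:
            raise ValueError("missing_day_prob must be in [0, 1)")
        if not 0.0 < self.emission_stay_prob <= 1.0:
            raise ValueError("emission_stay_prob must be in (0, 1]")
        if self.mean_duration_weeks < 1:
            raise ValueError("mean_duration_weeks must be >= 1")


@dataclass
class GroundTruth:
    """Planted latent weekly states keyed by (participant_id, week_start)."""

    states: Dict[Tuple[str, dt.date], int]
    transition: np.ndarray
    initial_state_probs: np.ndarray

    def frame(self) -> pd.DataFrame:
        rows = [
            (pid, ws.isoformat(), s) for (pid, ws), s in sorted(self.states.items())
        ]
        return pd.DataFrame(rows, columns=["participant_id", "week_start", "true_state"])


def emission_distributions(state_levels: Sequence[int], stay_prob: float):
    """Per-state ordinal emission (support, probs) around each anchor.

    Weight ``stay_prob`` sits on the anchor and (1-stay_prob)/2 on each of
    anchor+-1; values off the 1..5 scale are clipped away and the
    remaining mass renormalised.
    """
    out = []
    side = (1.0 - stay_prob) / 2.0
    for a in state_levels:
        support, probs = [], []
        for v, w in ((a - 1, side), (a, stay_prob), (a + 1, side)):
            if SCORE_MIN <= v <= SCORE_MAX and w > 0:
                support.append(v)
                probs.append(w)
        probs = np.asarray(probs) / np.sum(probs)
        out.append((np.asarray(support), probs))
    return out


def _tilted_initial(p0: np.ndarray, conditions, affinity: Dict[str, float]) -> np.ndarray:
    k = len(p0)
    tilt = sum(affinity.get(c, 0.0) for c in conditions)
    if tilt == 0.0 or k == 1:
        return p0
    weights = p0 * np.exp(tilt * (np.arange(k) / (k - 1)))
    return weights / weights.sum()


def generate_cohort(config: SyntheticConfig) -> Tuple[Dataset, GroundTruth]:
    """Simulate a cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    T = config.resolved_transition()
    p0 = config.resolved_initial()
    k = config.k_true
    emissions = emission_distributions(config.state_levels, config.emission_stay_prob)
    max_support = max(len(s) for s, _ in emissions)
    # padded per-state cumulative probabilities for vectorised sampling
    cum = np.ones((k, max_support))
    supp = np.zeros((k, max_support), dtype=int)
    for i, (s, p) in enumerate(emissions):
        cum[i, : len(p)] = np.cumsum(p)
        cum[i, len(p):] = 1.0
        supp[i, : len(s)] = s
        supp[i, len(s):] = s[-1]

    span_days = 7 * config.n_weeks_span
    sexes = list(config.sex_probs)
    sex_p = np.array([config.sex_probs[s] for s in sexes], dtype=float)
    sex_p = sex_p / sex_p.sum()
    ages = list(config.age_group_probs)
    age_p = np.array([config.age_group_probs[a] for a in ages], dtype=float)
    age_p = age_p / age_p.sum()
    cond_labels = list(config.condition_probs)
    cond_p = np.array([config.condition_probs[c] for c in cond_labels])

    records: List[DailyRecord] = []
    participants: List[Participant] = []
    truth: Dict[Tuple[str, dt.date], int] = {}

    for i in range(config.n_participants):
        pid = f"p{i:05d}"
        sex = sexes[rng.choice(len(sexes), p=sex_p)]
        age = ages[rng.choice(len(ages), p=age_p)]
        conds = frozenset(
            c for c, keep in zip(cond_labels, rng.random(len(cond_labels)) < cond_p) if keep
        )
        join = config.study_start + dt.timedelta(days=int(rng.integers(0, span_days)))
        weeks = int(rng.geometric(1.0 / config.mean_duration_weeks))
        last = min(join + dt.timedelta(days=7 * weeks - 1), config.study_end)

        first_ws = aligned_week_start(join, 0)
        n_chain = ((last - first_ws).days // 7) + 1
        states = np.empty(n_chain, dtype=int)
        states[0] = rng.choice(k, p=_tilted_initial(p0, conds, config.condition_affinity))
        for t in range(1, n_chain):
            states[t] = rng.choice(k, p=T[states[t - 1]])
        for t in range(n_chain):
            truth[(pid, first_ws + dt.timedelta(days=7 * t))] = int(states[t]) + 1

        n_days = (last - join).days + 1
        offsets = np.arange(n_days) + (join - first_ws).days
        day_states = states[offsets // 7]
        present = rng.random(n_days) >= config.missing_day_prob
        u = rng.random(n_days)
        idx = (u[:, None] > cum[day_states]).sum(axis=1)
        scores = supp[day_states, idx]
        for d in np.flatnonzero(present):
            records.append(
                DailyRecord(pid, join + dt.timedelta(days=int(d)), int(scores[d]))
            )
        participants.append(
            Participant(pid, sex, age, conds, join, last)
        )

    dataset = Dataset(records=records, participants=participants)
    return dataset, GroundTruth(states=truth, transition=T, initial_state_probs=p0)


def planted_partition_reference(ground_truth: GroundTruth, trajectories) -> np.ndarray:
    """True latent state (1-based) of each extracted complete week."""
    labels = np.empty(len(trajectories), dtype=int)
    for i, t in enumerate(trajectories):
        key = (t.participant_id, t.week_start)
        if key not in ground_truth.states:
            raise ValueError(f"no ground truth for trajectory {key}")
        labels[i] = ground_truth.states[key]
    return labels
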