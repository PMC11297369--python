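"""Cluster description: severity-ordered labels, shares, path weights,
per-participant time in cluster, and demographic group means with
participant-level bootstrap confidence intervals.

Clusters are lettered A, B, C, ... in ascending mean severity of their
center, so A is always the lowest-pain cluster.  Time in cluster is a
participant-level quantity (a participant's proportion of complete weeks
in each cluster); group summaries average it unweighted over the group's
participants, so a participant contributing many weeks counts once.
Condition groupings are multi-membership: a participant reporting several
conditions appears in each corresponding row.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cluster import ClusterSolution
from .datamodel import Participant, WeekTrajectory

GROUPINGS = ("all", "sex", "age_group", "condition")


def cluster_letters(n: int) -> List[str]:
    if n > 26:
        raise ValueError("more than 26 clusters are not supported for lettering")
    return list(string.ascii_uppercase[:n])


def label_clusters(solution: ClusterSolution) -> List[str]:
    """Letter per cluster index, ordered by ascending center mean severity.

    For the one-hot encoding the implied severity of a center is its
    decoded mean score.  Ties keep the original index order.
    """
    centers = np.asarray(solution.centers, dtype=float)
    if centers.shape[1] == 35:  # one-hot day-major blocks of 5 scores
        sev = centers.reshape(len(centers), 7, 5).argmax(axis=2).mean(axis=1) + 1
    else:
        sev = centers.mean(axis=1)
    order = np.argsort(sev, kind="stable")
    letters = cluster_letters(solution.k)
    out = [""] * solution.k
    for rank, idx in enumerate(order):
        out[idx] = letters[rank]
    return out


def assignment_letters(solution: ClusterSolution) -> np.ndarray:
    labels = label_clusters(solution)
    return np.array([labels[a] for a in solution.assignments])


def cluster_shares(solution: ClusterSolution) -> Dict[str, float]:
    """Percentage of trajectories per lettered cluster."""
    if len(solution.assignments) == 0:
        raise ValueError("solution has no assignments")
    labels = label_clusters(solution)
    counts = solution.counts()
    total = counts.sum()
    return {
        labels[c]: 100.0 * counts[c] / total
        for c in np.argsort([labels[c] for c in range(solution.k)])
    }


@dataclass
class ClusterProfile:
    """One cluster's label, size, share, center and weighted paths."""

    label: str
    size: int
    share_pct: float
    center: np.ndarray
    path_weights: Counter


def cluster_profiles(trajectories: Sequence[WeekTrajectory],
                     solution: ClusterSolution) -> List[ClusterProfile]:
    letters = label_clusters(solution)
    counts = solution.counts()
    total = counts.sum()
    profiles = []
    for c in np.argsort(letters, kind="stable"):
        members = [t for t, a in zip(trajectories, solution.assignments) if a == c]
        weights = Counter(tuple(t.scores) for t in members)
        profiles.append(
            ClusterProfile(
                label=letters[c],
                size=int(counts[c]),
                share_pct=100.0 * counts[c] / total,
                center=np.asarray(solution.centers[c]),
                path_weights=weights,
            )
        )
    return profiles


def proportions_from_labels(participant_ids: Sequence[str],
                            labels: Sequence[str]) -> pd.DataFrame:
    """Per-participant proportion of weeks per label, from flat label lists."""
    df = pd.DataFrame({"participant_id": list(participant_ids), "label": list(labels)})
    counts = df.groupby("participant_id")["label"].value_counts().unstack(fill_value=0)
    counts = counts.reindex(columns=sorted(counts.columns), fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def time_in_cluster(trajectories: Sequence[WeekTrajectory],
                    solution: ClusterSolution) -> pd.DataFrame:
    """Per-participant proportion of complete weeks in each lettered cluster.

    Rows index participants, columns the cluster letters; each row sums
    to 1.  Participants with zero extracted weeks do not appear.
    """
    letters = sorted(set(label_clusters(solution)))
    lab = assignment_letters(solution)
    out = proportions_from_labels([t.participant_id for t in trajectories], lab)
    return out.reindex(columns=letters, fill_value=0)


def group_members(participants: Sequence[Participant], grouping: str) -> Dict[str, List[str]]:
    """Participant ids per group value under a grouping scheme."""
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    groups: Dict[str, List[str]] = {}
    for p in participants:
        if grouping == "all":
            groups.setdefault("all", []).append(p.participant_id)
        elif grouping == "sex":
            groups.setdefault(p.sex, []).append(p.participant_id)
        elif grouping == "age_group":
            groups.setdefault(p.age_group, []).append(p.participant_id)
        else:  # condition: multi-membership
            for c in sorted(p.conditions):
                groups.setdefault(c, []).append(p.participant_id)
    return groups


def group_mean_time(proportions: pd.DataFrame,
                    participants: Sequence[Participant],
                    grouping: str) -> pd.DataFrame:
    """Unweighted participant-level mean time-in-cluster (%) per group."""
    groups = group_members(participants, grouping)
    rows = {}
    for g, pids in groups.items():
        pids = [p for p in pids if p in proportions.index]
        if not pids:
            continue
        rows[g] = 100.0 * proportions.loc[pids].mean(axis=0)
    return pd.DataFrame(rows).T


def bootstrap_ci(proportions: np.ndarray, B: int = 1000, level: float = 95.0,
                 seed: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CI for the group mean of each cluster column.

    Resamples participants (rows) with replacement ``B`` times and takes
    the (alpha/2, 1-alpha/2) percentiles of the resampled means.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100)")
    X = np.atleast_2d(np.asarray(proportions, dtype=float))
    if X.shape[0] == 1 and np.asarray(proportions).ndim == 1:
        X = np.asarray(proportions, dtype=float).reshape(-1, 1)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    means = X[idx].mean(axis=1)  # (B, k)
    alpha = (100.0 - level) / 2.0
    low = np.percentile(means, alpha, axis=0)
    high = np.percentile(means, 100.0 - alpha, axis=0)
    return low, high


@dataclass
class GroupTimeSummary:
    """Mean time in each cluster for one demographic group, with CIs."""

    grouping: str
    group: str
    n_participants: int
    mean_pct: Dict[str, float]
    ci_pct: Dict[str, Tuple[float, float]]


def group_time_summaries(proportions: pd.DataFrame,
                         participants: Sequence[Participant],
                         groupings: Sequence[str] = GROUPINGS,
                         B: int = 1000, level: float = 95.0,
                         seed: Optional[int] = None) -> List[GroupTimeSummary]:
    """Demographic table of mean time in cluster with bootstrap CIs."""
    out: List[GroupTimeSummary] = []
    offset = 0
    for grouping in groupings:
        groups = group_members(participants, grouping)
        for g in sorted(groups):
            pids = [p for p in groups[g] if p in proportions.index]
            if not pids:
                continue
            sub = proportions.loc[pids].to_numpy()
            mean = 100.0 * sub.mean(axis=0)
            lo, hi = bootstrap_ci(
                100.0 * sub, B=B, level=level,
                seed=None if seed is None else seed + offset,
            )
            cols = list(proportions.columns)
            out.append(
                GroupTimeSummary(
                    grouping=grouping,
                    group=g,
                    n_participants=len(pids),
                    mean_pct={c: float(m) for c, m in zip(cols, mean)},
                    ci_pct={c: (float(a), float(b)) for c, a, b in zip(cols, lo, hi)},
                )
            )
            offset += 1
    return out


def summaries_frame(summaries: Sequence[GroupTimeSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"grouping": s.grouping, "group": s.group, "n": s.n_participants}
        for c, m in s.mean_pct.items():
            lo, hi = s.ci_pct[c]
            row[f"{c}_mean"] = round(m, 1)
            row[f"{c}_ci_low"] = round(lo, 1)
            row[f"{c}_ci_high"] = round(hi, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def spaghetti_plot(profile: ClusterProfile, path) -> None:
    """Weighted spaghetti plot of one cluster's paths; center in red."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    wmax = max(profile.path_weights.values()) if profile.path_weights else 1
    days = np.arange(1, 8)
    for scores, w in profile.path_weights.items():
        ax.plot(days, scores, color="gray", alpha=0.15 + 0.8 * w / wmax,
                linewidth=0.5 + 2.5 * w / wmax)
    center = profile.center
    if len(center) == 35:
        center = center.reshape(7, 5).argmax(axis=1) + 1
    ax.plot(days, center, color="red", linewidth=2.0)
    ax.set_ylim(0.8, 5.2)
    ax.set_xlabel("day of week")
    ax.set_ylabel("pain severity")
    ax.set_title(f"Cluster {profile.label} ({profile.share_pct:.2f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
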