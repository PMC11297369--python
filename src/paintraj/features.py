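"""Feature encodings and distances for weekly trajectories.

Two encodings are used.  ``ordinal7`` keeps the week as its seven raw
scores, preserving both order and longitudinal structure; it is compared
with the Manhattan (L1) distance in the main analysis and the Euclidean
distance in the continuous-scale sensitivity analysis.  ``onehot35``
discards order: each (day, score) pair becomes a binary indicator (35
columns, day-major blocks of five scores, exactly one indicator set per
day), compared with the Jaccard distance.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial import distance as _sdist

from .datamodel import SCORE_MAX, SCORE_MIN, WeekTrajectory

N_DAYS = 7
N_SCORES = SCORE_MAX - SCORE_MIN + 1
ONEHOT_LEN = N_DAYS * N_SCORES

METRICS = ("manhattan", "euclidean", "jaccard")


def _as_vector(week) -> np.ndarray:
    if isinstance(week, WeekTrajectory):
        return np.asarray(week.scores, dtype=float)
    return np.asarray(week, dtype=float)


def ordinal_vector(week) -> np.ndarray:
    """Day-ordered 7-vector of scores (offset 0 = the aligned week start)."""
    v = _as_vector(week)
    if v.shape != (N_DAYS,):
        raise ValueError(f"a complete week has {N_DAYS} scores, got shape {v.shape}")
    if np.any((v < SCORE_MIN) | (v > SCORE_MAX)) or np.any(v != np.round(v)):
        raise ValueError("ordinal scores must be integers in 1..5")
    return v


def onehot_vector(week) -> np.ndarray:
    """One-hot (day, score) indicator vector; entry 5*d + (s-1) marks day d at score s."""
    v = ordinal_vector(week).astype(int)
    out = np.zeros(ONEHOT_LEN, dtype=int)
    out[N_SCORES * np.arange(N_DAYS) + (v - SCORE_MIN)] = 1
    return out


def encode_weeks(trajectories: Sequence, encoding: str = "ordinal7") -> np.ndarray:
    """Stack trajectories into an (n, 7) ordinal or (n, 35) one-hot matrix."""
    if encoding == "ordinal7":
        return np.array([ordinal_vector(t) for t in trajectories], dtype=float)
    if encoding == "onehot35":
        return np.array([onehot_vector(t) for t in trajectories], dtype=int)
    raise ValueError(f"unknown encoding {encoding!r}")


def _check_same_length(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")


def manhattan(a, b) -> float:
    """Sum of entry-wise absolute differences (exact integer on ordinal input)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    _check_same_length(a, b)
    return float(np.abs(a - b).sum())


def euclidean(a, b) -> float:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    _check_same_length(a, b)
    return float(np.sqrt(((a - b) ** 2).sum()))


def jaccard(a, b) -> float:
    """Jaccard distance 1 - |a AND b| / |a OR b| on binary vectors."""
    a, b = np.asarray(a), np.asarray(b)
    _check_same_length(a, b)
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("jaccard distance requires binary vectors")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(a, b).sum()
    return float(1.0 - inter / union)


def _is_onehot_block(X: np.ndarray) -> bool:
    if X.ndim != 2 or X.shape[1] != ONEHOT_LEN:
        return False
    if not np.isin(X, (0, 1)).all():
        return False
    blocks = X.reshape(len(X), N_DAYS, N_SCORES)
    return bool((blocks.sum(axis=2) == 1).all())


def pairwise_distances(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    """Cross-distance matrix between row sets A and B under a named metric.

    For one-hot week matrices the Jaccard distance reduces algebraically to
    a function of the number of matching days m (each vector has exactly
    one indicator per day block, so the union is 14 - m and the distance
    1 - m/(14 - m)); that form is used as an exact fast path.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if metric == "manhattan":
        return _sdist.cdist(A, B, "cityblock")
    if metric == "euclidean":
        return _sdist.cdist(A, B, "euclidean")
    if metric == "jaccard":
        if _is_onehot_block(A) and _is_onehot_block(B):
            codes_a = A.reshape(len(A), N_DAYS, N_SCORES).argmax(axis=2).astype(float)
            codes_b = B.reshape(len(B), N_DAYS, N_SCORES).argmax(axis=2).astype(float)
            mismatch = _sdist.cdist(codes_a, codes_b, "hamming") * N_DAYS
            m = N_DAYS - mismatch
            return 1.0 - m / (2 * N_DAYS - m)
        return _sdist.cdist(A.astype(bool), B.astype(bool), "jaccard")
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def distance(a, b, metric: str) -> float:
    """Scalar dispatch over the three named distances."""
    if metric == "manhattan":
        return manhattan(a, b)
    if metric == "euclidean":
        return euclidean(a, b)
    if metric == "jaccard":
        return jaccard(a, b)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
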