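"""Week-to-week transition analysis between clusters.

Over all consecutive complete-week pairs, the transition matrix counts
movement from the cluster held *last week* (rows) to the cluster held
*this week* (columns); percentages are row-normalised.  Under purely
random movement between k clusters every cell would be 100/k %, so
signed deviations from that uniform baseline highlight the stay/adjacent
structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .weeks import WeekPair


@dataclass
class TransitionMatrix:
    """Counts and row-percentages of cluster movement between weeks."""

    labels: List[str]
    counts: np.ndarray  # (k, k) ints, row = last week, column = this week

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k for k labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def percentages(self) -> np.ndarray:
        """Row-normalised percentages; rows with zero pairs are all-NaN."""
        row_sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / row_sums
        pct[np.repeat(row_sums == 0, len(self.labels), axis=1)] = np.nan
        return pct

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def percentages_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.percentages, index=self.labels, columns=self.labels)


def transition_matrix(pairs: Sequence[WeekPair],
                      assignment: Mapping[Tuple[str, object], str],
                      labels: Sequence[str] = None) -> TransitionMatrix:
    """Tally consecutive-week cluster movement.

    ``assignment`` maps (participant_id, week_start) to a cluster label;
    both weeks of every pair must be assigned.
    """
    lab_last, lab_this = [], []
    for p in pairs:
        for t, bucket in ((p.last_week, lab_last), (p.this_week, lab_this)):
            key = (t.participant_id, t.week_start)
            if key not in assignment:
                raise ValueError(f"trajectory {key} in a pair has no assignment")
            bucket.append(assignment[key])
    if labels is None:
        labels = sorted(set(lab_last) | set(lab_this))
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, b in zip(lab_last, lab_this):
        counts[index[a], index[b]] += 1
    return TransitionMatrix(labels=labels, counts=counts)


def assignment_map(trajectories, letters) -> Dict[Tuple[str, object], str]:
    """(participant_id, week_start) -> cluster letter, for pair lookup."""
    return {
        (t.participant_id, t.week_start): str(lab)
        for t, lab in zip(trajectories, letters)
    }


def stay_percentage(matrix: TransitionMatrix) -> Tuple[float, np.ndarray]:
    """Overall % of pairs staying in the same cluster, plus per-row diagonal %."""
    total = matrix.n_pairs
    if total == 0:
        raise ValueError("transition matrix has no pairs")
    diag = np.diag(matrix.counts).sum()
    overall = 100.0 * diag / total
    per_row = np.diag(matrix.percentages)
    return float(overall), per_row


def deviation_from_uniform(matrix: TransitionMatrix) -> np.ndarray:
    """Signed percentage-point deviation of each cell from the 100/k baseline."""
    k = len(matrix.labels)
    return matrix.percentages - 100.0 / k


def transition_heatmap(matrix: TransitionMatrix, path) -> None:
    """Diverging heatmap of deviations from the uniform baseline."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dev = deviation_from_uniform(matrix)
    pct = matrix.percentages
    fig, ax = plt.subplots(figsize=(4.5, 4))
    lim = np.nanmax(np.abs(dev)) or 1.0
    im = ax.imshow(dev, cmap="RdBu", vmin=-lim, vmax=lim)
    k = len(matrix.labels)
    ax.set_xticks(range(k), matrix.labels)
    ax.set_yticks(range(k), matrix.labels)
    ax.set_xlabel("this week")
    ax.set_ylabel("last week")
    for i in range(k):
        for j in range(k):
            if np.isfinite(pct[i, j]):
                ax.text(j, i, f"{pct[i, j]:.1f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="pp vs uniform")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
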