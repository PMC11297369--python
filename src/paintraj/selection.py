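"""Choosing the number of clusters k: WSS curve, elbow, size criterion.

k is selected with three criteria: (1) the elbow of the WSS-versus-k
curve, automated here as the k with maximal vertical deviation below the
chord joining the curve's endpoints (the visual elbow made reproducible;
the full deviation profile is always reported so a human can override);
(2) every cluster must hold at least 5% of the trajectories, with a
downward fallback to the nearest smaller k that passes; (3) clinical
interpretability, which is inherently manual — center summaries are
surfaced for review but never decided automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .cluster import ClusterSolution, best_of_runs


@dataclass
class ElbowResult:
    k: int
    deviations: Dict[int, float]


@dataclass
class SelectionReport:
    """Outcome of the k-selection procedure over a k range."""

    k_range: Tuple[int, int]
    wss_by_k: Dict[int, float]
    elbow_k: int
    deviations: Dict[int, float]
    size_ok_by_k: Dict[int, bool]
    smallest_share_by_k: Dict[int, float]
    chosen_k: int
    variability_explained_pct: float
    solutions: Dict[int, ClusterSolution] = field(default_factory=dict)

    @property
    def solution(self) -> ClusterSolution:
        return self.solutions[self.chosen_k]

    def summary(self) -> dict:
        return {
            "k_range": list(self.k_range),
            "wss_by_k": {str(k): v for k, v in self.wss_by_k.items()},
            "elbow_k": self.elbow_k,
            "chosen_k": self.chosen_k,
            "variability_explained_pct": self.variability_explained_pct,
            "size_ok_by_k": {str(k): bool(v) for k, v in self.size_ok_by_k.items()},
            "cluster_shares_pct": [round(s, 2) for s in self.solution.shares_pct()],
        }


def wss_curve(points, k_range=(1, 20), method: str = "clara",
              metric: str = "manhattan", n_runs: int = 20, base_seed: int = 0,
              warm_start: bool = True, wss_mode: Optional[str] = None,
              **kw) -> Dict[int, ClusterSolution]:
    """Best-of-runs solution per k over an inclusive k range.

    Seeds fan out per k as ``base_seed + 1000 * k``; with warm-start
    chaining enabled (default) each k also tries an initialisation built
    from the previous k's centers, which makes the curve non-increasing.
    """
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if k_min < 1 or k_max < k_min:
        raise ValueError(f"bad k_range {k_range}")
    n = len(points)
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds n={n}")
    # the scan cannot go past the number of distinct points (degenerate
    # inputs such as all-identical data cap the curve)
    n_distinct = len(np.unique(np.asarray(points, dtype=float), axis=0))
    k_max = min(k_max, n_distinct)
    if k_min > k_max:
        k_min = k_max
    solutions: Dict[int, ClusterSolution] = {}
    prev = None
    for k in range(k_min, k_max + 1):
        solutions[k] = best_of_runs(
            points, k, method=method, metric=metric, n_runs=n_runs,
            base_seed=base_seed + 1000 * k,
            warm_start=prev if warm_start else None,
            wss_mode=wss_mode, **kw,
        )
        prev = solutions[k]
    return solutions


def detect_elbow(wss_by_k: Mapping[int, float]) -> ElbowResult:
    """Elbow = k maximising vertical deviation below the endpoint chord.

    Requires at least three (k, WSS) points; ties and degenerate (e.g.
    linear) curves resolve to the smallest interior k.  The result is
    invariant to affine rescaling of the WSS axis.
    """
    ks = np.array(sorted(wss_by_k))
    if len(ks) < 3:
        raise ValueError("elbow detection needs at least 3 points on the curve")
    w = np.array([float(wss_by_k[k]) for k in ks])
    if not np.isfinite(w).all():
        raise ValueError("WSS curve contains non-finite values")
    k0, k1 = ks[0], ks[-1]
    w0, w1 = w[0], w[-1]
    chord = w0 + (w1 - w0) * (ks - k0) / (k1 - k0)
    dev = chord - w
    interior = slice(1, -1)
    deviations = {int(k): float(d) for k, d in zip(ks[interior], dev[interior])}
    best_k = ks[interior][np.argmax(dev[interior])]  # argmax ties -> smallest k
    return ElbowResult(k=int(best_k), deviations=deviations)


def min_cluster_size_ok(solution: ClusterSolution,
                        threshold_pct: float = 5.0) -> Tuple[bool, float]:
    """Whether every cluster holds at least ``threshold_pct`` of trajectories."""
    shares = solution.shares_pct()
    smallest = float(shares.min())
    return smallest >= threshold_pct, smallest


def variability_explained(wss_k: float, wss_1: float) -> float:
    """Percentage of variability described by the k-cluster solution.

    100 * (1 - WSS_k / WSS_1), reported to one decimal place.
    """
    if wss_1 <= 0:
        raise ValueError("wss_1 must be positive")
    if not (0 <= wss_k <= wss_1):
        raise ValueError("need 0 <= wss_k <= wss_1")
    return round(100.0 * (1.0 - wss_k / wss_1), 1)


def elbow_plot(report: "SelectionReport", path) -> None:
    """WSS-vs-k curve with the detected elbow marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = sorted(report.wss_by_k)
    w = [report.wss_by_k[k] for k in ks]
    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.plot(ks, w, marker="o", ms=3)
    ax.axvline(report.elbow_k, color="red", ls="--", lw=1,
               label=f"elbow k={report.elbow_k}")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("WSS")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def select_k(points, k_range=(1, 20), method: str = "clara",
             metric: str = "manhattan", threshold_pct: float = 5.0,
             n_runs: int = 20, base_seed: int = 0, warm_start: bool = True,
             wss_mode: Optional[str] = None, force_k: Optional[int] = None,
             **kw) -> SelectionReport:
    """Full k-selection: WSS curve, elbow, size criterion with downward fallback."""
    solutions = wss_curve(points, k_range, method=method, metric=metric,
                          n_runs=n_runs, base_seed=base_seed,
                          warm_start=warm_start, wss_mode=wss_mode, **kw)
    ks = sorted(solutions)
    curve = {k: solutions[k].wss for k in ks}
    size_ok = {}
    smallest_share = {}
    for k in ks:
        ok, share = min_cluster_size_ok(solutions[k], threshold_pct)
        size_ok[k] = ok
        smallest_share[k] = share

    w = np.array([curve[k] for k in ks])
    degenerate = len(ks) < 3 or (w.max() - w.min()) <= 1e-9 * max(w.max(), 1.0)
    if degenerate:
        elbow_k, deviations = ks[0], {}
    else:
        res = detect_elbow(curve)
        elbow_k, deviations = res.k, res.deviations

    if force_k is not None:
        if force_k not in solutions:
            raise ValueError(f"force_k={force_k} outside the evaluated range")
        chosen = int(force_k)
    else:
        chosen = None
        for k in range(elbow_k, ks[0] - 1, -1):
            if size_ok.get(k, False):
                chosen = k
                break
        if chosen is None:
            raise ValueError(
                "no k in the range passes the minimum-cluster-size criterion; "
                f"smallest shares by k: {smallest_share}"
            )

    wss_1 = curve.get(ks[0]) if ks[0] == 1 else None
    if wss_1 and wss_1 > 0:
        var_pct = variability_explained(curve[chosen], wss_1)
    else:
        var_pct = float("nan")

    return SelectionReport(
        k_range=(ks[0], ks[-1]),
        wss_by_k=curve,
        elbow_k=int(elbow_k),
        deviations=deviations,
        size_ok_by_k=size_ok,
        smallest_share_by_k=smallest_share,
        chosen_k=int(chosen),
        variability_explained_pct=var_pct,
        solutions=solutions,
    )
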