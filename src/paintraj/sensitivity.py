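"""Sensitivity analyses and cross-solution agreement scoring.

Three analyses probe the main k-medoids/Manhattan result: (1) treat the
scale as continuous and longitudinal (k-means with mean centers under the
Euclidean distance); (2) treat it as unordered categorical (one-hot
(day, score) indicators with the Jaccard distance, clustered by CLARA);
(3) redefine the week to start on each of the seven days.  Analyses 1 and
2 are scored by the percentage of trajectories assigned to corresponding
clusters after optimal label matching (plus the adjusted Rand index);
analysis 3 compares cluster share distributions only, because the week
sets differ by construction across start days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.cluster import contingency_matrix

from .cluster import ClusterSolution
from .describe import cluster_shares, label_clusters
from .features import encode_weeks
from .selection import SelectionReport, select_k
from .weeks import WEEKDAY_NAMES, extract_complete_weeks


def match_clusters(sol_a: ClusterSolution, sol_b: ClusterSolution
                   ) -> Tuple[Dict[int, int], float]:
    """Optimal cluster correspondence between two solutions and its agreement.

    The mapping (injective over the smaller label set) maximises the total
    number of trajectories placed in corresponding clusters, found by
    optimal assignment on the contingency table.  Returns the mapping from
    solution-a cluster indices to solution-b cluster indices and the
    agreement percentage.
    """
    a = np.asarray(sol_a.assignments)
    b = np.asarray(sol_b.assignments)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("solutions must cover the same non-empty trajectory set")
    C = contingency_matrix(a, b)
    rows, cols = linear_sum_assignment(-C)
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    agreement = 100.0 * C[rows, cols].sum() / len(a)
    return mapping, float(agreement)


def severity_rank_agreement(sol_a: ClusterSolution, sol_b: ClusterSolution) -> Optional[float]:
    """Agreement when clusters are matched by severity rank instead.

    Only defined when both solutions have the same k; by construction it
    can never exceed the optimal-assignment agreement.
    """
    if sol_a.k != sol_b.k:
        return None
    la = np.asarray(label_clusters(sol_a))
    lb = np.asarray(label_clusters(sol_b))
    a = la[np.asarray(sol_a.assignments)]
    b = lb[np.asarray(sol_b.assignments)]
    return float(100.0 * np.mean(a == b))


@dataclass
class AgreementReport:
    """Cross-solution comparison for one sensitivity analysis."""

    analysis: str
    chosen_k: int
    mapping: Dict[int, int]
    agreement_pct: float
    ari: float
    severity_rank_agreement_pct: Optional[float]
    selection: SelectionReport = field(repr=False, default=None)

    def summary(self) -> dict:
        return {
            "analysis": self.analysis,
            "chosen_k": self.chosen_k,
            "agreement_pct": round(self.agreement_pct, 2),
            "ari": round(self.ari, 4),
            "severity_rank_agreement_pct": (
                None if self.severity_rank_agreement_pct is None
                else round(self.severity_rank_agreement_pct, 2)
            ),
        }


def _agreement_report(name: str, report: SelectionReport,
                      main_solution: ClusterSolution) -> AgreementReport:
    sol = report.solution
    mapping, agreement = match_clusters(sol, main_solution)
    ari = adjusted_rand_score(main_solution.assignments, sol.assignments)
    return AgreementReport(
        analysis=name,
        chosen_k=report.chosen_k,
        mapping=mapping,
        agreement_pct=agreement,
        ari=float(ari),
        severity_rank_agreement_pct=severity_rank_agreement(sol, main_solution),
        selection=report,
    )


def run_sensitivity_1(trajectories, main_solution: ClusterSolution,
                      base_seed: int = 0, k_range=(1, 20), n_runs: int = 20,
                      threshold_pct: float = 5.0) -> AgreementReport:
    """Continuous-scale analysis: longitudinal k-means, Euclidean distance."""
    X = encode_weeks(trajectories, "ordinal7")
    report = select_k(X, k_range=k_range, method="kml", n_runs=n_runs,
                      base_seed=base_seed, threshold_pct=threshold_pct)
    return _agreement_report("sensitivity_1_kml_euclidean", report, main_solution)


def run_sensitivity_2(trajectories, main_solution: ClusterSolution,
                      base_seed: int = 0, k_range=(1, 20), n_runs: int = 20,
                      threshold_pct: float = 5.0) -> AgreementReport:
    """Categorical analysis: one-hot (day, score) features, Jaccard, CLARA."""
    X = encode_weeks(trajectories, "onehot35")
    report = select_k(X, k_range=k_range, method="clara", metric="jaccard",
                      n_runs=n_runs, base_seed=base_seed,
                      threshold_pct=threshold_pct)
    return _agreement_report("sensitivity_2_onehot_jaccard", report, main_solution)


def run_sensitivity_3(dataset, base_seed: int = 0, k_range=(1, 20),
                      n_runs: int = 20, threshold_pct: float = 5.0
                      ) -> Dict[str, dict]:
    """Day-of-week analysis: re-extract and recluster for each start day.

    Returns, per start day, the selection report and the cluster share
    table.  No per-trajectory matching is attempted (the week sets
    differ), mirroring a share-distribution comparison.
    """
    out: Dict[str, dict] = {}
    for d, name in enumerate(WEEKDAY_NAMES):
        weeks = extract_complete_weeks(dataset, week_start_day=d)
        if len(weeks) < k_range[1]:
            out[name] = {"n_weeks": len(weeks), "report": None, "shares": None}
            continue
        X = encode_weeks(weeks, "ordinal7")
        report = select_k(X, k_range=k_range, method="clara", metric="manhattan",
                          n_runs=n_runs, base_seed=base_seed + d,
                          threshold_pct=threshold_pct)
        out[name] = {
            "n_weeks": len(weeks),
            "report": report,
            "shares": cluster_shares(report.solution),
        }
    return out
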