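import datetime as dt

import numpy as np
import pandas as pd
import pytest

from paintraj.cluster import ClusterSolution, kmedoids
from paintraj.datamodel import Participant
from paintraj.describe import (bootstrap_ci, cluster_profiles, cluster_shares,
                               group_mean_time, group_time_summaries,
                               label_clusters, proportions_from_labels,
                               time_in_cluster)
from paintraj.features import encode_weeks
from .conftest import MONDAY, make_week


def solution_with_centers(centers, assignments):
    centers = np.asarray(centers, dtype=float)
    return ClusterSolution(
        k=len(centers), method="kmedoids", metric="manhattan",
        centers=centers, assignments=np.asarray(assignments),
        wss=0.0, wss_mode="to_center",
    )


def participant(pid, sex="female", age="45-54", conds=()):
    return Participant(pid, sex, age, frozenset(conds),
                       MONDAY, MONDAY + dt.timedelta(days=400))


class TestLabels:
    def test_letters_follow_center_severity(self):
        sol = solution_with_centers([[1] * 7, [3] * 7, [2] * 7], [0, 1, 2])
        assert label_clusters(sol) == ["A", "C", "B"]

    def test_single_cluster_is_A(self):
        sol = solution_with_centers([[4] * 7], [0, 0])
        assert label_clusters(sol) == ["A"]

    def test_equal_centers_stable_order(self):
        sol = solution_with_centers([[2] * 7, [2] * 7], [0, 1])
        assert label_clusters(sol) == ["A", "B"]


class TestShares:
    def test_published_share_arithmetic(self):
        counts = (1714, 8246, 8376, 3583)  # of 21,919 trajectories
        assignments = np.repeat(np.arange(4), counts)
        sol = solution_with_centers([[1] * 7, [2] * 7, [3] * 7, [4] * 7],
                                    assignments)
        shares = cluster_shares(sol)
        assert shares["A"] == pytest.approx(7.82, abs=0.005)
        assert shares["B"] == pytest.approx(37.62, abs=0.005)
        assert shares["C"] == pytest.approx(38.21, abs=0.005)
        assert shares["D"] == pytest.approx(16.35, abs=0.005)
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_profiles_path_weights_sum_to_size(self):
        weeks = [make_week(f"p{i}", scores=(lvl,) * 7)
                 for i, lvl in enumerate([1, 1, 2, 5, 5, 5])]
        sol = kmedoids(encode_weeks(weeks), 2, seed=0)
        for prof in cluster_profiles(weeks, sol):
            assert sum(prof.path_weights.values()) == prof.size


class TestTimeInCluster:
    def test_proportions(self):
        pids = ["p1"] * 8
        labels = ["A", "A", "B", "B", "B", "B", "B", "B"]
        props = proportions_from_labels(pids, labels)
        assert props.loc["p1", "A"] == pytest.approx(0.25)
        assert props.loc["p1"].sum() == pytest.approx(1.0)

    def test_all_weeks_one_cluster(self):
        props = proportions_from_labels(["p1"] * 5 + ["p2"], ["A"] * 5 + ["B"])
        assert props.loc["p1", "A"] == 1.0 and props.loc["p1", "B"] == 0.0

    def test_group_mean_is_participant_weighted(self):
        # duplicating a participant's weeks must not change the group mean
        base = proportions_from_labels(["p1", "p1", "p2"], ["A", "B", "A"])
        dup = proportions_from_labels(["p1"] * 4 + ["p2"], ["A", "B"] * 2 + ["A"])
        parts = [participant("p1"), participant("p2")]
        m1 = group_mean_time(base, parts, "all")
        m2 = group_mean_time(dup, parts, "all")
        pd.testing.assert_frame_equal(m1, m2)
        assert m1.loc["all", "A"] == pytest.approx(75.0)

    def test_two_participant_example(self):
        props = proportions_from_labels(["p1", "p1", "p2", "p2"],
                                        ["B", "B", "A", "B"])
        parts = [participant("p1"), participant("p2")]
        m = group_mean_time(props, parts, "all")
        assert m.loc["all", "A"] == pytest.approx(25.0)  # mean of 0% and 50%

    def test_condition_grouping_is_multi_membership(self):
        props = proportions_from_labels(["p1", "p2"], ["A", "B"])
        parts = [participant("p1", conds=("fibromyalgia", "gout")),
                 participant("p2", conds=("gout",))]
        m = group_mean_time(props, parts, "condition")
        assert set(m.index) == {"fibromyalgia", "gout"}
        assert m.loc["fibromyalgia", "A"] == pytest.approx(100.0)
        assert m.loc["gout", "A"] == pytest.approx(50.0)

    def test_unknown_grouping_rejected(self):
        props = proportions_from_labels(["p1"], ["A"])
        with pytest.raises(ValueError, match="grouping"):
            group_mean_time(props, [participant("p1")], "height")


class TestBootstrap:
    def test_identical_rows_zero_width(self):
        props = np.tile([0.2, 0.8], (10, 1))
        lo, hi = bootstrap_ci(props, B=200, seed=0)
        np.testing.assert_allclose(lo, [0.2, 0.8])
        np.testing.assert_allclose(hi, [0.2, 0.8])

    def test_interval_brackets_mean_and_is_ordered(self):
        rng = np.random.default_rng(1)
        props = rng.dirichlet([2, 3, 4], size=40)
        lo, hi = bootstrap_ci(props, B=500, seed=2)
        mean = props.mean(axis=0)
        assert np.all(lo <= hi)
        assert np.all(lo <= mean) and np.all(mean <= hi)

    def test_endpoints_monotone_in_level(self):
        rng = np.random.default_rng(3)
        props = rng.dirichlet([2, 2], size=30)
        lo90, hi90 = bootstrap_ci(props, B=400, level=90, seed=4)
        lo99, hi99 = bootstrap_ci(props, B=400, level=99, seed=4)
        assert np.all(lo99 <= lo90) and np.all(hi90 <= hi99)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        props = rng.dirichlet([1, 2, 3], size=25)
        assert np.array_equal(bootstrap_ci(props, B=100, seed=9),
                              bootstrap_ci(props, B=100, seed=9))

    def test_invalid_B_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.ones((3, 2)), B=0)


def test_group_time_summaries_shape(small_cohort):
    _, dataset, _, weeks = small_cohort
    sol = kmedoids(encode_weeks(weeks), 4, seed=0)
    props = time_in_cluster(weeks, sol)
    np.testing.assert_allclose(props.sum(axis=1), 1.0)
    summaries = group_time_summaries(props, dataset.participants, B=100, seed=0)
    for s in summaries:
        for c, m in s.mean_pct.items():
            lo, hi = s.ci_pct[c]
            assert lo <= m + 1e-9 and m <= hi + 1e-9
    groupings = {s.grouping for s in summaries}
    assert groupings == {"all", "sex", "age_group", "condition"}
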