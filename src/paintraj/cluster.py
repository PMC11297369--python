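"""k-medoids, CLARA and longitudinal k-means clustering of week vectors.

The medoid of a cluster is the member minimising the total distance to
all other members, so centers remain observed, interpretable weeks (no
fractional "pain 3.2" centers).  The k-medoids algorithm implemented here
is the alternating (Voronoi) variant: starting from k randomly chosen
distinct points it repeatedly (1) assigns every point to its nearest
medoid and (2) recomputes each cluster's medoid, until the assignment
stabilises.  CLARA wraps it for large n by running it on random
subsamples and keeping the medoid set with the lowest full-data cost.
The longitudinal k-means variant (KmL-style) replaces medoids with
coordinate-wise means under the Euclidean distance.

All estimators follow the scikit-learn protocol (``fit``, ``predict``,
``labels_``, ``cluster_centers_``, ``inertia_``) and all randomness flows
from explicit seeds; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .features import pairwise_distances

WSS_MODES = ("to_center", "to_center_squared", "pairwise")

_DEFAULT_WSS_MODE = {
    "kmedoids": "to_center",
    "clara": "to_center",
    "kmedoids_clara": "to_center",
    "kml": "to_center_squared",
    "kmeans_longitudinal": "to_center_squared",
}


def _validate_points(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("points must be a non-empty 2-D array")
    if not np.isfinite(X).all():
        raise ValueError("points must be finite")
    return X


def _distinct_rows(X: np.ndarray):
    """Unique rows plus, for each, the lowest original row index."""
    _, first_idx = np.unique(X, axis=0, return_index=True)
    return np.sort(first_idx)


def _nearest(X: np.ndarray, centers: np.ndarray, metric: str):
    D = pairwise_distances(X, centers, metric)
    labels = D.argmin(axis=1)  # ties -> lowest center index
    return labels, D


class KMedoids(ClusterMixin, BaseEstimator):
    """Alternating k-medoids under a named metric.

    Parameters
    ----------
    n_clusters : number of clusters k (must not exceed the number of
        distinct points).
    metric : 'manhattan' (default), 'euclidean' or 'jaccard'.
    max_iter : iteration cap for the assign/update alternation.
    random_state : seed for the uniform draw of initial medoids from the
        distinct points; ignored when ``init_medoids`` is given.
    init_medoids : optional explicit initial medoid row indices.
    swap_refine : if True, run a greedy medoid/non-medoid swap pass after
        convergence (off by default; the alternating scheme alone is the
        documented algorithm).

    Attributes (after ``fit``)
    --------------------------
    cluster_centers_ : (k, d) medoid vectors, each an observed data row.
    medoid_indices_ : row indices of the medoids in the training data.
    labels_ : cluster index per training point.
    inertia_ : sum of distances of points to their medoid.
    objective_history_ : assignment-step objective per iteration
        (non-increasing).
    converged_ : whether the assignment stabilised within ``max_iter``.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        metric: str = "manhattan",
        max_iter: int = 100,
        random_state: Optional[int] = None,
        init_medoids: Optional[Sequence[int]] = None,
        swap_refine: bool = False,
    ):
        self.n_clusters = n_clusters
        self.metric = metric
        self.max_iter = max_iter
        self.random_state = random_state
        self.init_medoids = init_medoids
        self.swap_refine = swap_refine

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        X = _validate_points(X)
        k = int(self.n_clusters)
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        distinct = _distinct_rows(X)
        if k > len(distinct):
            raise ValueError(
                f"n_clusters={k} exceeds the {len(distinct)} distinct points"
            )

        if self.init_medoids is not None:
            medoids = np.asarray(self.init_medoids, dtype=int)
            if len(medoids) != k:
                raise ValueError("init_medoids must have length n_clusters")
        else:
            rng = np.random.default_rng(self.random_state)
            medoids = distinct[rng.choice(len(distinct), size=k, replace=False)]

        history = []
        labels = None
        converged = False
        for _ in range(int(self.max_iter)):
            new_labels, D = _nearest(X, X[medoids], self.metric)
            history.append(float(D[np.arange(len(X)), new_labels].sum()))
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(new_labels == c)
                if len(members) == 0:
                    continue  # keep previous medoid for an emptied cluster
                Dm = pairwise_distances(X[members], X[members], self.metric)
                # members is ascending, so argmin ties break to the lowest
                # original row index
                new_medoids[c] = members[Dm.sum(axis=0).argmin()]
            if labels is not None and np.array_equal(new_labels, labels) and np.array_equal(
                new_medoids, medoids
            ):
                converged = True
                labels = new_labels
                break
            labels = new_labels
            medoids = new_medoids

        # make labels consistent with the final medoid set
        labels, D = _nearest(X, X[medoids], self.metric)
        inertia = float(D[np.arange(len(X)), labels].sum())

        if self.swap_refine:
            medoids, labels, inertia = self._swap_refine(X, distinct, medoids, inertia)

        self.cluster_centers_ = X[medoids].copy()
        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = inertia
        self.objective_history_ = history
        self.converged_ = converged
        self.n_iter_ = len(history)
        return self

    def _swap_refine(self, X, distinct, medoids, inertia, max_passes: int = 20):
        medoids = medoids.copy()
        for _ in range(max_passes):
            best = (None, None, inertia)
            for pos in range(len(medoids)):
                for cand in distinct:
                    if cand in medoids:
                        continue
                    trial = medoids.copy()
                    trial[pos] = cand
                    D = pairwise_distances(X, X[trial], self.metric)
                    cost = float(D.min(axis=1).sum())
                    if cost < best[2] - 1e-12:
                        best = (pos, cand, cost)
            if best[0] is None:
                break
            medoids[best[0]] = best[1]
            inertia = best[2]
        labels, D = _nearest(X, X[medoids], self.metric)
        return medoids, labels, float(D[np.arange(len(X)), labels].sum())

    def predict(self, X):
        X = _validate_points(X)
        labels, _ = _nearest(X, self.cluster_centers_, self.metric)
        return labels


class CLARA(ClusterMixin, BaseEstimator):
    """CLARA: k-medoids on random subsamples, scored on the full data.

    Each of ``n_samples`` subsamples (drawn uniformly without replacement,
    indices kept in ascending order so tie-breaks by original index carry
    over) is clustered with :class:`KMedoids`; every point of the full
    data set is then assigned to the resulting medoids, and the medoid set
    with the lowest full-data distance-to-medoid cost is retained.  With
    ``sample_size >= n`` and ``n_samples=1`` this reduces exactly to a
    single :class:`KMedoids` run with the same seed.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        metric: str = "manhattan",
        n_samples: int = 5,
        sample_size: Optional[int] = None,
        max_iter: int = 100,
        random_state: Optional[int] = None,
    ):
        self.n_clusters = n_clusters
        self.metric = metric
        self.n_samples = n_samples
        self.sample_size = sample_size
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _validate_points(X)
        n = len(X)
        k = int(self.n_clusters)
        distinct = _distinct_rows(X)
        if k > len(distinct):
            raise ValueError(
                f"n_clusters={k} exceeds the {len(distinct)} distinct points"
            )
        size = self.sample_size
        if size is None:
            size = min(n, 40 + 2 * k)
        if size < k:
            raise ValueError(f"sample_size={size} must be >= n_clusters={k}")
        size = min(size, n)

        sub_rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 997
        )
        best = None
        for s in range(int(self.n_samples)):
            idx = self._draw_subsample(X, distinct, n, size, k, sub_rng)
            seed = None if self.random_state is None else self.random_state + s
            km = KMedoids(
                n_clusters=k,
                metric=self.metric,
                max_iter=self.max_iter,
                random_state=seed,
            ).fit(X[idx])
            medoids = idx[km.medoid_indices_]
            labels, D = _nearest(X, X[medoids], self.metric)
            cost = float(D[np.arange(n), labels].sum())
            if best is None or cost < best[0] - 1e-12:
                best = (cost, medoids, labels, km.converged_)

        cost, medoids, labels, converged = best
        self.cluster_centers_ = X[medoids].copy()
        self.medoid_indices_ = medoids
        self.labels_ = labels
        self.inertia_ = cost
        self.converged_ = converged
        return self

    @staticmethod
    def _draw_subsample(X, distinct, n, size, k, rng):
        if size >= n:
            return np.arange(n)
        for _ in range(10):
            idx = np.sort(rng.choice(n, size=size, replace=False))
            if len(np.unique(X[idx], axis=0)) >= k:
                return idx
        # heavily duplicated data: guarantee k distinct rows are present
        extra = [i for i in distinct if i not in set(idx)][: k]
        return np.sort(np.unique(np.concatenate([idx, extra])))[:max(size, k)]

    def predict(self, X):
        X = _validate_points(X)
        labels, _ = _nearest(X, self.cluster_centers_, self.metric)
        return labels


class LongitudinalKMeans(ClusterMixin, BaseEstimator):
    """k-means over whole week vectors (KmL-style), Euclidean distance.

    Identical alternation to k-medoids except the cluster center is the
    coordinate-wise mean of its members (centers may be fractional).  An
    emptied cluster is re-seeded at the point farthest from its nearest
    current center.
    """

    def __init__(
        self,
        n_clusters: int = 4,
        max_iter: int = 100,
        random_state: Optional[int] = None,
        init_centers: Optional[np.ndarray] = None,
    ):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.random_state = random_state
        self.init_centers = init_centers

    def fit(self, X, y=None):
        X = _validate_points(X)
        n = len(X)
        k = int(self.n_clusters)
        distinct = _distinct_rows(X)
        if k > len(distinct):
            raise ValueError(
                f"n_clusters={k} exceeds the {len(distinct)} distinct points"
            )
        if self.init_centers is not None:
            centers = np.asarray(self.init_centers, dtype=float).copy()
            if centers.shape != (k, X.shape[1]):
                raise ValueError("init_centers must be (n_clusters, n_features)")
        else:
            rng = np.random.default_rng(self.random_state)
            centers = X[distinct[rng.choice(len(distinct), size=k, replace=False)]].copy()

        labels = None
        converged = False
        for _ in range(int(self.max_iter)):
            D = pairwise_distances(X, centers, "euclidean")
            new_labels = D.argmin(axis=1)
            # re-seed emptied clusters at the point farthest from its
            # nearest center (each empty cluster takes the next-farthest)
            empties = [c for c in range(k) if not np.any(new_labels == c)]
            if empties:
                order = np.argsort(-D.min(axis=1), kind="stable")
                taken = 0
                for c in empties:
                    far = order[taken]
                    new_labels[far] = c
                    taken += 1
            for c in range(k):
                members = new_labels == c
                centers[c] = X[members].mean(axis=0)
            if labels is not None and np.array_equal(new_labels, labels):
                converged = True
                labels = new_labels
                break
            labels = new_labels

        D = pairwise_distances(X, centers, "euclidean")
        labels = D.argmin(axis=1)
        self.cluster_centers_ = centers
        self.labels_ = labels
        self.inertia_ = float((D[np.arange(n), labels] ** 2).sum())
        self.converged_ = converged
        return self

    def predict(self, X):
        X = _validate_points(X)
        D = pairwise_distances(X, self.cluster_centers_, "euclidean")
        return D.argmin(axis=1)


# -- solution container and functional layer ------------------------------


@dataclass
class ClusterSolution:
    """One clustering of a fixed trajectory set plus its run metadata."""

    k: int
    method: str  # 'kmedoids_clara' | 'kmeans_longitudinal' | 'kmedoids'
    metric: str
    centers: np.ndarray
    assignments: np.ndarray  # cluster index (0..k-1) per trajectory
    wss: float
    wss_mode: str
    n_runs: int = 1
    seed: Optional[int] = None
    converged: bool = True
    medoid_indices: Optional[np.ndarray] = None

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)

    def shares_pct(self) -> np.ndarray:
        return 100.0 * self.counts() / len(self.assignments)


def wss(points, solution: ClusterSolution, mode: Optional[str] = None) -> float:
    """Within-cluster dispersion of a solution over its points.

    ``to_center``: sum of distances to the assigned center;
    ``to_center_squared``: sum of squared distances to the assigned center;
    ``pairwise``: sum over clusters of all unordered within-cluster pair
    distances.
    """
    mode = mode or solution.wss_mode
    if mode not in WSS_MODES:
        raise ValueError(f"unknown wss mode {mode!r}; expected one of {WSS_MODES}")
    X = _validate_points(points)
    labels = np.asarray(solution.assignments)
    if mode == "pairwise":
        total = 0.0
        for c in range(solution.k):
            members = X[labels == c]
            if len(members) < 2:
                continue
            Dm = pairwise_distances(members, members, solution.metric)
            total += float(Dm.sum()) / 2.0
        return total
    D = pairwise_distances(X, solution.centers, solution.metric)
    d = D[np.arange(len(X)), labels]
    return float((d ** 2).sum()) if mode == "to_center_squared" else float(d.sum())


def _solution_from_estimator(est, method: str, metric: str, seed, wss_mode: str,
                             n_runs: int = 1) -> ClusterSolution:
    if wss_mode == "to_center":
        w = float(est.inertia_) if method != "kmeans_longitudinal" else None
    else:
        w = None
    sol = ClusterSolution(
        k=int(est.n_clusters),
        method=method,
        metric=metric,
        centers=np.asarray(est.cluster_centers_),
        assignments=np.asarray(est.labels_),
        wss=0.0,
        wss_mode=wss_mode,
        n_runs=n_runs,
        seed=seed,
        converged=bool(getattr(est, "converged_", True)),
        medoid_indices=getattr(est, "medoid_indices_", None),
    )
    if w is None:
        w = wss(est._fit_X_, sol, wss_mode) if hasattr(est, "_fit_X_") else None
    sol.wss = w
    return sol


def kmedoids(points, k, metric: str = "manhattan", seed: Optional[int] = None,
             max_iter: int = 100, init_medoids=None, wss_mode: str = "to_center",
             swap_refine: bool = False) -> ClusterSolution:
    X = _validate_points(points)
    est = KMedoids(
        n_clusters=k, metric=metric, max_iter=max_iter, random_state=seed,
        init_medoids=init_medoids, swap_refine=swap_refine,
    ).fit(X)
    est._fit_X_ = X
    sol = _solution_from_estimator(est, "kmedoids", metric, seed, wss_mode)
    if sol.wss is None:
        sol.wss = wss(X, sol, wss_mode)
    return sol


def clara(points, k, metric: str = "manhattan", n_samples: int = 5,
          sample_size: Optional[int] = None, seed: Optional[int] = None,
          max_iter: int = 100, wss_mode: str = "to_center") -> ClusterSolution:
    X = _validate_points(points)
    est = CLARA(
        n_clusters=k, metric=metric, n_samples=n_samples,
        sample_size=sample_size, max_iter=max_iter, random_state=seed,
    ).fit(X)
    est._fit_X_ = X
    sol = _solution_from_estimator(est, "kmedoids_clara", metric, seed, wss_mode)
    if sol.wss is None:
        sol.wss = wss(X, sol, wss_mode)
    return sol


def kmeans_longitudinal(points, k, seed: Optional[int] = None, max_iter: int = 100,
                        init_centers=None,
                        wss_mode: str = "to_center_squared") -> ClusterSolution:
    X = _validate_points(points)
    est = LongitudinalKMeans(
        n_clusters=k, max_iter=max_iter, random_state=seed, init_centers=init_centers,
    ).fit(X)
    est._fit_X_ = X
    sol = ClusterSolution(
        k=int(k), method="kmeans_longitudinal", metric="euclidean",
        centers=est.cluster_centers_, assignments=est.labels_,
        wss=0.0, wss_mode=wss_mode, seed=seed, converged=est.converged_,
    )
    sol.wss = float(est.inertia_) if wss_mode == "to_center_squared" else wss(X, sol, wss_mode)
    return sol


_METHODS = {
    "kmedoids": kmedoids,
    "clara": clara,
    "kml": kmeans_longitudinal,
}


def _run_method(method: str, X, k, seed, metric, wss_mode, **kw) -> ClusterSolution:
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(_METHODS)}")
    if method == "kml":
        return kmeans_longitudinal(X, k, seed=seed, wss_mode=wss_mode, **kw)
    return _METHODS[method](X, k, metric=metric, seed=seed, wss_mode=wss_mode, **kw)


def farthest_point(X, centers, metric: str) -> int:
    """Index of the point farthest from its nearest center (ties -> lowest)."""
    D = pairwise_distances(X, centers, metric)
    return int(D.min(axis=1).argmax())


def best_of_runs(points, k, method: str = "clara", metric: str = "manhattan",
                 n_runs: int = 20, base_seed: int = 0,
                 warm_start: Optional[ClusterSolution] = None,
                 wss_mode: Optional[str] = None, **kw) -> ClusterSolution:
    """Repeat a clustering ``n_runs`` times and keep the lowest-WSS solution.

    Runs use seeds ``base_seed .. base_seed + n_runs - 1`` (the restart
    protocol: random starting medoids add volatility, mitigated by
    repetition).  If ``warm_start`` is a solution at k-1 on the same
    points, one extra run is initialised from its centers plus the point
    farthest from its nearest center, which guarantees the selected WSS
    at k cannot exceed the one at k-1.  Ties break to the lowest seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X = _validate_points(points)
    wss_mode = wss_mode or _DEFAULT_WSS_MODE[method]

    candidates = []
    for i in range(int(n_runs)):
        candidates.append(_run_method(method, X, k, base_seed + i, metric, wss_mode, **kw))
    if warm_start is not None:
        if warm_start.k != k - 1:
            raise ValueError("warm_start must be a solution at k-1")
        far = farthest_point(X, warm_start.centers, metric if method != "kml" else "euclidean")
        if method == "kml":
            init = np.vstack([warm_start.centers, X[far]])
            candidates.append(
                kmeans_longitudinal(X, k, seed=base_seed + n_runs,
                                    init_centers=init, wss_mode=wss_mode)
            )
        else:
            if warm_start.medoid_indices is None:
                raise ValueError("warm_start for medoid methods needs medoid_indices")
            init = np.concatenate([warm_start.medoid_indices, [far]])
            candidates.append(
                kmedoids(X, k, metric=metric, seed=base_seed + n_runs,
                         init_medoids=init, wss_mode=wss_mode, **{
                             key: v for key, v in kw.items() if key in ("max_iter",)
                         })
            )
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.wss < best.wss - 1e-12:
            best = cand
    best.n_runs = len(candidates)
    best.method = {"clara": "kmedoids_clara", "kml": "kmeans_longitudinal",
                   "kmedoids": "kmedoids"}[method]
    return best
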