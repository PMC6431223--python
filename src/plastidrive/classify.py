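"""Inheritance-strength classification from transmission frequencies.

Plastomes are classified into discrete inheritance-strength classes from
their biparental transmission frequencies (percent variegated F1
seedlings in one or more cross series).  The procedure is two-step:

1. the number of classes k is estimated data-driven by partitioning
   around medoids (PAM) over a candidate range, keeping the k with the
   largest average silhouette width;
2. final classes come from Euclidean k-means at that k (or a user-forced
   k), with many seeded restarts, relabelled so that class 1 is the
   strongest plastome class.

The data-driven k is advisory: for some data sets a coarser or finer k
may be preferred on external grounds, so a forced k is accepted — but
never chosen automatically by anything other than the silhouette.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "pam",
    "estimate_k",
    "InheritanceKMeans",
    "kmeans_classify",
    "swap_rate",
]


def pam(X: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids (BUILD + SWAP), Euclidean distance.

    Deterministic: BUILD greedily seeds medoids; SWAP exhaustively tries
    all (medoid, non-medoid) exchanges until no swap lowers the total
    within-cluster distance.

    Returns ``(medoid_indices, labels)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} invalid for {n} points")
    D = squareform(pdist(X))
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids_arr = np.array(sorted(medoids))
    # SWAP
    def cost(meds: np.ndarray) -> float:
        return float(D[:, meds].min(axis=1).sum())

    best_cost = cost(medoids_arr)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids_arr:
                    continue
                trial = medoids_arr.copy()
                trial[mi] = h
                c = cost(trial)
                if c < best_cost - 1e-12:
                    medoids_arr, best_cost = np.sort(trial), c
                    improved = True
        if not improved:
            break
    labels = np.argmin(D[:, medoids_arr], axis=1)
    return medoids_arr, labels


def estimate_k(
    X, k_range=range(2, 11)
) -> tuple[int, dict[int, float]]:
    """Estimate the number of inheritance classes by PAM + silhouette.

    For each candidate k, clusters with :func:`pam` and records the
    average silhouette width; returns the argmax k and the full map.
    Candidate k values exceeding n - 1 are skipped.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError(f"no feasible k in range for n={n} samples")
    silhouette_by_k: dict[int, float] = {}
    for k in ks:
        _, labels = pam(X, k)
        if len(np.unique(labels)) < 2:
            silhouette_by_k[k] = -1.0
            continue
        silhouette_by_k[k] = float(silhouette_score(X, labels, metric="euclidean"))
    k_star = max(silhouette_by_k, key=lambda k: (silhouette_by_k[k], -k))
    return k_star, silhouette_by_k


class InheritanceKMeans(BaseEstimator, ClusterMixin):
    """k-means classifier of plastid inheritance strength.

    Clusters samples' transmission-frequency profiles with Euclidean
    k-means.  With ``n_clusters="auto"`` the number of classes is chosen
    by PAM average silhouette width over ``k_range`` first.  Classes are
    relabelled 1..k by the mean of their center coordinates so that
    class 1 is the strongest class: with ``strong_direction="low"``
    (the convention for crosses where a low percent-biparental marks an
    assertive maternal plastome) class 1 has the lowest center mean.

    Parameters
    ----------
    n_clusters : int or "auto"
    k_range : iterable of int, candidate k when auto.
    n_restarts : int, seeded k-means initialisations; best inertia kept.
    standardize : bool, z-score columns before clustering (off: the
        cross series share percent units).
    strong_direction : {"low", "high"}, which end of the frequency scale
        is the strong class.
    random_state : int or None.

    Attributes
    ----------
    k_ : chosen number of classes.
    labels_ : array of class labels in 1..k.
    cluster_centers_ : centers on the original (unstandardized) scale,
        ordered by class label.
    silhouette_by_k_ : dict, present when ``n_clusters="auto"``.
    inertia_ : within-cluster sum of squares of the kept run.
    """

    def __init__(
        self,
        n_clusters="auto",
        k_range=tuple(range(2, 11)),
        n_restarts: int = 100,
        standardize: bool = False,
        strong_direction: str = "low",
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.standardize = standardize
        self.strong_direction = strong_direction
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = len(X)
        Xw = X
        if self.standardize:
            sd = X.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xw = (X - X.mean(axis=0)) / sd
        if self.n_clusters == "auto":
            k, self.silhouette_by_k_ = estimate_k(Xw, self.k_range)
        else:
            k = int(self.n_clusters)
        if k < 2:
            raise ValueError(f"need k >= 2, got {k}")
        if k > n - 1:
            raise ValueError(f"k={k} too large for n={n} samples")
        if k > len(np.unique(Xw, axis=0)):
            raise ValueError(f"k={k} exceeds the number of distinct points")
        km = KMeans(
            n_clusters=k,
            n_init=self.n_restarts,
            random_state=self.random_state,
            algorithm="lloyd",
        ).fit(Xw)
        centers = km.cluster_centers_
        if self.standardize:
            centers = centers * sd + X.mean(axis=0)
        order = np.argsort(centers.mean(axis=1))
        if self.strong_direction == "high":
            order = order[::-1]
        elif self.strong_direction != "low":
            raise ValueError(f"unknown strong_direction {self.strong_direction!r}")
        relabel = np.empty(k, dtype=int)
        relabel[order] = np.arange(1, k + 1)
        self.k_ = k
        self.labels_ = relabel[km.labels_]
        self.cluster_centers_ = centers[order]
        self.inertia_ = float(km.inertia_)
        self._km = km
        self._relabel = relabel
        self._scale = (X.mean(axis=0), sd) if self.standardize else None
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self._scale is not None:
            mu, sd = self._scale
            X = (X - mu) / sd
        return self._relabel[self._km.predict(X)]

    def distance_to_center(self, X) -> np.ndarray:
        """Euclidean distance of each sample to its assigned class center."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        labels = self.predict(X)
        d = cdist(X, self.cluster_centers_)
        return d[np.arange(len(X)), labels - 1]


def kmeans_classify(
    profiles,
    k,
    n_restarts: int = 100,
    seed=None,
    strong_direction: str = "low",
) -> InheritanceKMeans:
    """Fit :class:`InheritanceKMeans` at a fixed or auto-selected k."""
    return InheritanceKMeans(
        n_clusters=k,
        n_restarts=n_restarts,
        random_state=seed,
        strong_direction=strong_direction,
    ).fit(profiles)


def swap_rate(labels_a, labels_b) -> float:
    """Minimal fraction of samples whose class differs between two
    clusterings, minimised over all label permutations.

    Zero iff the clusterings are identical up to relabelling; used to
    judge the stability of a forced k across repeated seeded runs.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    ua, ub = np.unique(a), np.unique(b)
    if len(ua) != len(ub):
        raise ValueError(f"cluster count mismatch: {len(ua)} vs {len(ub)}")
    k = len(ua)
    agree = np.zeros((k, k))
    for i, ca in enumerate(ua):
        for j, cb in enumerate(ub):
            agree[i, j] = np.sum((a == ca) & (b == cb))
    rows, cols = linear_sum_assignment(-agree)
    return 1.0 - agree[rows, cols].sum() / len(a)
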