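"""K-means archetype discovery on pooled hourly usage vectors.

Days enter as raw minutes-per-hour vectors (18 coordinates at the
default window, all in the same units, hence unstandardized).  The
cluster count is chosen by an automated elbow rule - the k whose point
on the normalized within-SS curve is farthest from the chord joining
the curve's endpoints - and the solution is evaluated with the
silhouette coefficient SC = (b - a) / max(a, b), where a is the mean
distance to same-cluster points and b the mean distance to the nearest
other cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

MAX_LLOYD_ITER = 300


@dataclass
class ClusterModel:
    """A fitted k-means solution with its sum-of-squares bookkeeping."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    within_ss: np.ndarray  # per cluster
    total_ss: float

    @property
    def within_ss_total(self) -> float:
        return float(self.within_ss.sum())

    @property
    def proportions(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k) / len(self.labels)

    @property
    def explained_variance(self) -> float:
        """Between-cluster share of the total sum of squares."""
        if self.total_ss == 0:
            return 0.0
        return 1.0 - self.within_ss_total / self.total_ss


def _as_matrix(vectors) -> np.ndarray:
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must be a 2-D array-like of day profiles")
    return X


def kmeans_fit(vectors, k: int, restarts: int = 25, seed: int = 0) -> ClusterModel:
    """Best-of-restarts Lloyd k-means with k-means++ seeding.

    Deterministic given ``seed``.  Requires at least k distinct vectors.
    """
    X = _as_matrix(vectors)
    n_distinct = len(np.unique(X, axis=0))
    if k < 1 or k > n_distinct:
        raise ValueError(f"k must be in [1, {n_distinct}] (distinct vectors), got {k}")
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        max_iter=MAX_LLOYD_ITER,
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    return _model_from(X, km.cluster_centers_, km.labels_)


def _model_from(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> ClusterModel:
    k = centroids.shape[0]
    diffs = X - centroids[labels]
    sq = np.einsum("ij,ij->i", diffs, diffs)
    within = np.bincount(labels, weights=sq, minlength=k)
    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    return ClusterModel(k=k, centroids=centroids, labels=np.asarray(labels), within_ss=within, total_ss=total_ss)


def wss_curve(vectors, k_max: int, restarts: int = 25, seed: int = 0) -> tuple[np.ndarray, list[ClusterModel]]:
    """Normalized within-SS curve for k = 1..k_max, monotone by construction.

    If the best-of-restarts fit for k is worse than for k-1 (rare), the
    fit is repeated warm-started from the incumbent centroids plus the
    point farthest from its centroid, so the curve never increases.
    """
    X = _as_matrix(vectors)
    models: list[ClusterModel] = []
    curve = np.empty(k_max)
    for k in range(1, k_max + 1):
        model = kmeans_fit(X, k, restarts=restarts, seed=seed)
        if models and model.within_ss_total > models[-1].within_ss_total:
            prev = models[-1]
            diffs = X - prev.centroids[prev.labels]
            far = X[np.argmax(np.einsum("ij,ij->i", diffs, diffs))]
            init = np.vstack([prev.centroids, far])
            km = KMeans(
                n_clusters=k, init=init, n_init=1, max_iter=MAX_LLOYD_ITER,
                algorithm="lloyd", random_state=seed,
            ).fit(X)
            warm = _model_from(X, km.cluster_centers_, km.labels_)
            if warm.within_ss_total < model.within_ss_total:
                model = warm
        models.append(model)
        curve[k - 1] = model.within_ss_total / model.total_ss if model.total_ss else 0.0
    return curve, models


@dataclass(frozen=True)
class ElbowResult:
    k: int
    chord_distances: np.ndarray
    no_elbow: bool
    linear_fit_residual: float


def elbow_select(wss_norm: np.ndarray) -> ElbowResult:
    """Automated elbow: k maximizing distance to the endpoint chord.

    ``wss_norm`` holds the normalized within-SS for k = 1..k_max.  The
    selected k is the interior point with maximum perpendicular offset
    below the chord joining (1, w_1) and (k_max, w_kmax); ties go to the
    smaller k.  A perfectly linear curve has zero offset everywhere and
    is flagged ``no_elbow``.  Also reports the residual of a straight
    line fitted through the tail beyond the selected k, the diagnostic
    used when the elbow is judged visually.
    """
    w = np.asarray(wss_norm, dtype=float)
    k_max = len(w)
    if k_max < 3:
        raise ValueError("elbow selection needs k_max >= 3 (an interior point)")
    ks = np.arange(1, k_max + 1)
    slope = (w[-1] - w[0]) / (k_max - 1)
    chord = w[0] + slope * (ks - 1)
    dist = chord - w  # positive when the curve sags below the chord
    k = int(ks[np.argmax(dist)])
    no_elbow = bool(np.max(dist) <= 1e-12)
    tail = ks >= k
    if tail.sum() >= 2:
        coef = np.polyfit(ks[tail], w[tail], 1)
        resid = float(np.sqrt(np.mean((np.polyval(coef, ks[tail]) - w[tail]) ** 2)))
    else:  # pragma: no cover - k_max >= 3 guarantees a tail
        resid = 0.0
    return ElbowResult(k=k, chord_distances=dist, no_elbow=no_elbow, linear_fit_residual=resid)


def silhouette(vectors, labels) -> np.ndarray:
    """Per-point silhouette coefficients SC = (b - a)/max(a, b).

    a is the mean Euclidean distance to the other members of the point's
    own cluster, b the smallest mean distance to another cluster.
    Members of singleton clusters get SC = 0 by convention.  Requires at
    least two non-empty clusters.
    """
    X = _as_matrix(vectors)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    D = cdist(X, X)
    n = len(X)
    sc = np.zeros(n)
    sums = np.stack([D[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    counts = np.array([(labels == c).sum() for c in uniq])
    own = np.searchsorted(uniq, labels)
    for i in range(n):
        c = own[i]
        if counts[c] == 1:
            sc[i] = 0.0
            continue
        a = sums[i, c] / (counts[c] - 1)
        other = np.delete(np.arange(len(uniq)), c)
        b = np.min(sums[i, other] / counts[other])
        denom = max(a, b)
        sc[i] = 0.0 if denom == 0 else (b - a) / denom
    return sc


@dataclass
class ClusterReport:
    """Per-cluster summary table plus mean hourly profiles with CI bands."""

    table: pd.DataFrame
    mean_profiles: np.ndarray  # (k, n_hours)
    ci_half_width: np.ndarray  # (k, n_hours), 95% normal approximation


def cluster_report(model: ClusterModel, vectors) -> ClusterReport:
    """Summarize a fitted model: proportions, silhouettes, mean profiles."""
    X = _as_matrix(vectors)
    sc = silhouette(X, model.labels) if model.k >= 2 else np.zeros(len(X))
    rows = []
    profiles = np.zeros((model.k, X.shape[1]))
    ci = np.zeros_like(profiles)
    for c in range(model.k):
        member = model.labels == c
        n = int(member.sum())
        prof = X[member]
        profiles[c] = prof.mean(axis=0)
        if n > 1:
            ci[c] = 1.96 * prof.std(axis=0, ddof=1) / np.sqrt(n)
        rows.append(
            {
                "cluster": c,
                "n_days": n,
                "proportion": n / len(X),
                "silhouette_mean": float(sc[member].mean()) if n else np.nan,
                "silhouette_sd": float(sc[member].std(ddof=1)) if n > 1 else 0.0,
                "peak_hour_index": int(np.argmax(profiles[c])),
            }
        )
    return ClusterReport(table=pd.DataFrame(rows), mean_profiles=profiles, ci_half_width=ci)
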