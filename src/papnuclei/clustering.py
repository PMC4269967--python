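"""Two-cluster classification of region descriptors.

Both clustering routines are written out in full because their update
rules are the decision mechanism of the method: Lloyd k-means minimises
the within-cluster sum of squared distances, and fuzzy c-means (FCM)
alternates the Bezdek membership update

    u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1))

with u^m-weighted centroid means until the largest membership change
drops below a tolerance.  Features are typically z-score standardised
first (the two minima-based features span tens of pixels while the
shape features are order one, so raw Euclidean distance would be
dominated by texture).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from papnuclei.features import FeatureVector, feature_matrix

__all__ = [
    "ClusterModel",
    "OverlapCall",
    "standardize",
    "kmeans_fit",
    "fcm_fit",
    "fcm_memberships",
    "call_overlap",
    "classify_features",
]

#: descriptor indices used by the overlap-calling rule
_IDX_AXIS_RATIO = 1
_IDX_N_MINIMA = 3
_IDX_MAX_DIST = 4


@dataclass
class ClusterModel:
    """Fitted two-cluster model over feature space.

    ``memberships`` is (N, k); rows are one-hot for k-means and sum to 1
    for FCM.  ``objective_history`` records the objective after each
    iteration of the returned run (within-cluster sum of squares for
    k-means, the fuzzy objective sum u^m d^2 for FCM).
    """

    method: str
    centroids: np.ndarray
    memberships: np.ndarray
    fuzzifier_m: float | None
    iterations_run: int
    converged: bool
    objective: float
    objective_history: list[float]


@dataclass
class OverlapCall:
    region_label: int
    predicted: str            # "single" | "overlapped"
    confidence: float         # max membership, in [0.5, 1] for 2 clusters


def standardize(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column z-scoring; zero-variance columns are left unscaled."""
    x = np.asarray(points, float)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (x - mean) / std, mean, std


def _validate_points(points: np.ndarray, k: int) -> np.ndarray:
    x = np.asarray(points, float)
    if x.ndim != 2:
        raise ValueError("points must be a 2-D matrix")
    if not np.isfinite(x).all():
        raise ValueError("points must be finite")
    if len(x) < k:
        raise ValueError(f"need at least {k} points for {k} clusters")
    return x


def _kmeanspp_init(x: np.ndarray, k: int,
                   rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: subsequent centres drawn with probability
    proportional to squared distance from the chosen set."""
    centroids = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min(
            ((x[:, None, :] - np.array(centroids)[None]) ** 2).sum(-1), axis=1)
        total = d2.sum()
        if total <= 0:
            centroids.append(x[rng.integers(len(x))])
        else:
            centroids.append(x[rng.choice(len(x), p=d2 / total)])
    return np.array(centroids)


def _sq_dists(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    return ((x[:, None, :] - centroids[None]) ** 2).sum(-1)


def kmeans_fit(
    points: np.ndarray,
    k: int = 2,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 300,
    rng_seed: int = 0,
) -> ClusterModel:
    """Lloyd k-means, best of ``n_restarts`` k-means++ seedings.

    The within-cluster sum of squares is non-increasing across Lloyd
    iterations; iteration stops when assignments stabilise or the
    centroid shift falls below ``tol``.  An emptied cluster is re-seeded
    at the point farthest from its assigned centroid.
    """
    x = _validate_points(points, k)
    rng = np.random.default_rng(rng_seed)
    best: ClusterModel | None = None
    for _ in range(n_restarts):
        centroids = _kmeanspp_init(x, k, rng)
        history: list[float] = []
        converged = False
        assign = None
        for it in range(1, max_iter + 1):
            d2 = _sq_dists(x, centroids)
            new_assign = d2.argmin(axis=1)
            for j in range(k):
                if not (new_assign == j).any():
                    worst = int(np.argmax(d2[np.arange(len(x)), new_assign]))
                    new_assign[worst] = j
            new_centroids = np.array(
                [x[new_assign == j].mean(axis=0) for j in range(k)])
            history.append(float(
                ((x - new_centroids[new_assign]) ** 2).sum()))
            shift = np.abs(new_centroids - centroids).max()
            stable = assign is not None and (new_assign == assign).all()
            centroids, assign = new_centroids, new_assign
            if stable or shift < tol:
                converged = True
                break
        memberships = np.zeros((len(x), k))
        memberships[np.arange(len(x)), assign] = 1.0
        model = ClusterModel("kmeans", centroids, memberships, None,
                             len(history), converged, history[-1], history)
        if best is None or model.objective < best.objective:
            best = model
    return best


def fcm_memberships(points: np.ndarray, centroids: np.ndarray,
                    m: float) -> np.ndarray:
    """Closed-form membership update from centroids (the inverse
    squared-distance ratio rule).  A point coinciding with a centroid
    gets membership 1 there and 0 elsewhere."""
    x = np.asarray(points, float)
    d2 = _sq_dists(x, centroids)
    u = np.zeros_like(d2)
    zero = d2 <= 0
    singular = zero.any(axis=1)
    if singular.any():
        first = zero[singular].argmax(axis=1)
        u[np.nonzero(singular)[0], first] = 1.0
    ok = ~singular
    if ok.any():
        p = 1.0 / (m - 1.0)
        inv = d2[ok] ** -p
        u[ok] = inv / inv.sum(axis=1, keepdims=True)
    return u


def fcm_fit(
    points: np.ndarray,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    rng_seed: int = 0,
) -> ClusterModel:
    """Fuzzy c-means with fuzzifier ``m`` (> 1).

    Centroids are seeded k-means++-style; memberships and centroids then
    alternate until the largest absolute membership change is below
    ``tol`` or ``max_iter`` is reached.
    """
    if m <= 1.0:
        raise ValueError("fuzzifier m must be > 1")
    x = _validate_points(points, c)
    rng = np.random.default_rng(rng_seed)
    centroids = _kmeanspp_init(x, c, rng)
    u = fcm_memberships(x, centroids, m)
    history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        um = u ** m
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        new_u = fcm_memberships(x, centroids, m)
        history.append(float((new_u ** m * _sq_dists(x, centroids)).sum()))
        change = np.abs(new_u - u).max()
        u = new_u
        if change < tol:
            converged = True
            break
    return ClusterModel("fcm", centroids, u, m, iterations, converged,
                        history[-1], history)


def call_overlap(model: ClusterModel,
                 features: list[FeatureVector]) -> list[OverlapCall]:
    """Assign each region its max-membership cluster and name the
    clusters.

    Overlapping produces extra intensity valleys, so the cluster whose
    centroid has the larger n_minima coordinate is the overlapped one
    (ties broken by max_minima_dist, then axis_ratio).  This holds in
    whichever (raw or standardised) space the model was fitted, since
    z-scoring is monotone per coordinate.
    """
    valid = [f for f in features if f.valid]
    if model.memberships.shape[0] != len(valid):
        raise ValueError("model was not fitted on these features")
    c = model.centroids
    for idx in (_IDX_N_MINIMA, _IDX_MAX_DIST, _IDX_AXIS_RATIO):
        diff = c[:, idx].max() - c[:, idx].min()
        if diff > 1e-12:
            overlapped_cluster = int(c[:, idx].argmax())
            break
    else:
        raise ValueError("clusters indistinguishable: centroids tie on "
                         "n_minima, max_minima_dist and axis_ratio")
    calls = []
    for row, fv in zip(model.memberships, valid):
        j = int(row.argmax())
        calls.append(OverlapCall(
            region_label=fv.region_label,
            predicted="overlapped" if j == overlapped_cluster else "single",
            confidence=float(row[j]),
        ))
    return calls


def classify_features(
    features: list[FeatureVector],
    method: str = "fcm",
    standardize_first: bool = True,
    fuzzifier_m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    n_restarts: int = 10,
    rng_seed: int = 0,
) -> tuple[ClusterModel, list[OverlapCall]]:
    """Fit the requested model on a feature list and call overlaps."""
    x = feature_matrix(features)
    if standardize_first:
        x, _, _ = standardize(x)
    if method == "kmeans":
        model = kmeans_fit(x, k=2, n_restarts=n_restarts, tol=tol,
                           max_iter=max_iter, rng_seed=rng_seed)
    elif method == "fcm":
        model = fcm_fit(x, c=2, m=fuzzifier_m, tol=tol, max_iter=max_iter,
                        rng_seed=rng_seed)
    else:
        raise ValueError(f"unknown clustering method: {method!r}")
    return model, call_overlap(model, features)
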