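"""K-means clustering, K-means++ seeding, and the fireworks-seeded hybrid.

K-means is written from first principles around an explicit contract:
Euclidean distance, centroid update by within-cluster means, and the
sum-of-squared-errors (SSE) loss

    L = sum_i sum_{x in c_i} |x - c_i|^2

which both the plain iteration and the fireworks optimizer minimize.  The
hybrid :func:`fwa_kmeans` encodes a complete set of K centroids as one flat
position vector, lets the fireworks algorithm search the data's bounding box
for a low-SSE centroid set, and refines the best one with standard K-means —
addressing K-means' sensitivity to initialization and its tendency to converge
to local optima.

:func:`exhaustive_optimal_partition` provides a brute-force optimum for tiny
instances and serves as the independent oracle in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, List, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .fwa import FWAConfig, fwa_minimize

__all__ = [
    "ClusteringError",
    "KMeansConfig",
    "ClusteringResult",
    "euclidean_distance",
    "assign_points",
    "update_centroids",
    "sse_loss",
    "kmeans",
    "kmeanspp_init",
    "decode_centroids",
    "encode_centroids",
    "centroid_search_bounds",
    "clustering_objective",
    "fwa_kmeans",
    "exhaustive_optimal_partition",
]

#: Hard cap on the number of set partitions the brute-force oracle will score.
MAX_ORACLE_PARTITIONS = 100_000


class ClusteringError(ValueError):
    """Invalid input for a clustering operation."""


@dataclass
class KMeansConfig:
    """K-means settings: cluster count, iteration cap, and the relative
    loss-change threshold that triggers convergence."""

    K: int
    max_iterations: int = 100
    loss_tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ClusteringError("K must be a positive integer")
        if self.max_iterations < 1:
            raise ClusteringError("max_iterations must be a positive integer")
        if self.loss_tolerance < 0:
            raise ClusteringError("loss_tolerance must be non-negative")


@dataclass
class ClusteringResult:
    """Converged centroids, per-sample labels, SSE loss, and run metadata.

    ``loss`` always equals ``sse_loss(data, centroids, labels)`` for the data
    the result was computed on; ``loss_history`` is the per-iteration loss
    sequence (non-increasing).
    """

    centroids: np.ndarray
    labels: np.ndarray
    loss: float
    iterations_run: int
    converged: bool
    loss_history: List[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return int(self.centroids.shape[0])

    def to_dict(self) -> dict:
        return {
            "centroids": [[float(v) for v in row] for row in self.centroids],
            "labels": [int(v) for v in self.labels],
            "loss": float(self.loss),
            "iterations_run": int(self.iterations_run),
            "converged": bool(self.converged),
            "loss_history": [float(v) for v in self.loss_history],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ClusteringResult":
        return cls(
            centroids=np.asarray(d["centroids"], dtype=float),
            labels=np.asarray(d["labels"], dtype=int),
            loss=float(d["loss"]),
            iterations_run=int(d["iterations_run"]),
            converged=bool(d["converged"]),
            loss_history=[float(v) for v in d.get("loss_history", [])],
        )


def _as_data(data) -> np.ndarray:
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ClusteringError("data must be a non-empty n x d matrix")
    if not np.all(np.isfinite(X)):
        raise ClusteringError("data contains non-finite values")
    return X


def euclidean_distance(x, y) -> float:
    """Euclidean distance ``sqrt(sum (x_i - y_i)^2)`` between two vectors."""
    a = np.asarray(x, dtype=float).ravel()
    b = np.asarray(y, dtype=float).ravel()
    if a.size != b.size:
        raise ClusteringError(f"length mismatch: {a.size} vs {b.size}")
    return float(np.linalg.norm(a - b))


def assign_points(data, centroids) -> np.ndarray:
    """Label every sample with its nearest centroid (ties: lowest index)."""
    X = _as_data(data)
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    if X.shape[1] != C.shape[1]:
        raise ClusteringError(
            f"dimension mismatch: data has d={X.shape[1]}, centroids d={C.shape[1]}"
        )
    return np.argmin(cdist(X, C), axis=1)


def _means_with_repair(X: np.ndarray, labels: np.ndarray, K: int) -> Tuple[np.ndarray, np.ndarray]:
    """Within-cluster means; empty clusters are re-seeded with the sample
    farthest from its own centroid (taken from a donor cluster of size > 1)."""
    n, d = X.shape
    if K > n:
        raise ClusteringError(f"cannot form K={K} non-empty clusters from n={n} samples")
    labels = np.asarray(labels, dtype=int).copy()
    if labels.shape != (n,):
        raise ClusteringError("assignment length must equal the number of samples")
    if labels.min() < 0 or labels.max() >= K:
        raise ClusteringError(f"labels must lie in [0, {K})")
    while True:
        counts = np.bincount(labels, minlength=K)
        centers = np.zeros((K, d))
        for k in np.flatnonzero(counts > 0):
            centers[k] = X[labels == k].mean(axis=0)
        empties = np.flatnonzero(counts == 0)
        if empties.size == 0:
            return centers, labels
        dist_own = np.linalg.norm(X - centers[labels], axis=1)
        dist_own[counts[labels] <= 1] = -np.inf  # singletons cannot donate
        donor = int(np.argmax(dist_own))
        if not np.isfinite(dist_own[donor]):
            raise ClusteringError(
                f"cannot repair empty cluster {int(empties[0])}: all clusters are singletons"
            )
        labels[donor] = int(empties[0])


def update_centroids(data, assignment, K: int) -> np.ndarray:
    """Centroid update: each center becomes the mean of its assigned samples.

    An empty cluster is re-seeded with the single sample currently farthest
    from its own centroid (removed from its donor cluster), then means are
    recomputed.
    """
    X = _as_data(data)
    centers, _ = _means_with_repair(X, assignment, K)
    return centers


def sse_loss(data, centroids, assignment) -> float:
    """Sum over clusters of squared Euclidean distances of members to their
    centroid (the loss both K-means and the fireworks search minimize)."""
    X = _as_data(data)
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    labels = np.asarray(assignment, dtype=int)
    if labels.shape[0] != X.shape[0]:
        raise ClusteringError("assignment length must equal the number of samples")
    diffs = X - C[labels]
    return float(np.sum(diffs * diffs))


def kmeans(data, config: KMeansConfig, initial_centroids) -> ClusteringResult:
    """Lloyd iteration from explicit initial centroids.

    Alternates nearest-centroid assignment and mean update until the relative
    loss change drops to ``loss_tolerance`` or ``max_iterations`` is reached.
    The per-iteration loss sequence is non-increasing (each half-step is an
    exact minimization of the SSE in its own argument).
    """
    X = _as_data(data)
    centers = np.atleast_2d(np.asarray(initial_centroids, dtype=float)).copy()
    K = centers.shape[0]
    if K != config.K:
        raise ClusteringError(f"initial_centroids has K={K} but config.K={config.K}")
    if K > X.shape[0]:
        raise ClusteringError(f"K={K} exceeds number of samples n={X.shape[0]}")

    loss_history: List[float] = []
    prev_loss = None
    converged = False
    labels = assign_points(X, centers)
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        labels = assign_points(X, centers)
        centers, labels = _means_with_repair(X, labels, K)
        loss = sse_loss(X, centers, labels)
        loss_history.append(loss)
        if prev_loss is not None:
            rel_change = (prev_loss - loss) / max(prev_loss, np.finfo(float).tiny)
            if rel_change <= config.loss_tolerance:
                converged = True
                break
        prev_loss = loss
    return ClusteringResult(
        centroids=centers,
        labels=labels,
        loss=loss_history[-1],
        iterations_run=iterations,
        converged=converged,
        loss_history=loss_history,
    )


def kmeanspp_init(data, K: int, rng: np.random.Generator) -> np.ndarray:
    """K-means++ seeding: first center uniform over samples, each subsequent
    center drawn with probability proportional to its squared distance to the
    nearest already-chosen center (D^2 weighting)."""
    X = _as_data(data)
    n = X.shape[0]
    if K > n:
        raise ClusteringError(f"K={K} exceeds number of samples n={n}")
    centers = np.empty((K, X.shape[1]))
    first = int(rng.integers(n))
    centers[0] = X[first]
    closest_sq = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, K):
        total = closest_sq.sum()
        if total <= 0:
            # all remaining points coincide with chosen centers
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=closest_sq / total))
        centers[j] = X[idx]
        closest_sq = np.minimum(closest_sq, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def decode_centroids(position, K: int, d: int) -> np.ndarray:
    """Row-major reshape of a flat length-``K*d`` vector into K centers."""
    pos = np.asarray(position, dtype=float).ravel()
    if pos.size != K * d:
        raise ClusteringError(f"position length {pos.size} != K*d = {K * d}")
    return pos.reshape(K, d)


def encode_centroids(centroids) -> np.ndarray:
    """Flatten a K x d centroid matrix into a search-space position."""
    return np.asarray(centroids, dtype=float).ravel()


def centroid_search_bounds(data, K: int) -> np.ndarray:
    """Per-dimension [column-min, column-max] of the data, tiled K times —
    the box the fireworks search explores (centers outside the data hull are
    never SSE-optimal).  Constant columns get a half-unit pad so the box has
    positive width."""
    X = _as_data(data)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    flat = hi - lo <= 0
    lo = np.where(flat, lo - 0.5, lo)
    hi = np.where(flat, hi + 0.5, hi)
    return np.tile(np.column_stack([lo, hi]), (K, 1))


def clustering_objective(data, K: int) -> Callable[[np.ndarray], float]:
    """SSE of a flat-encoded centroid set under nearest assignment — the
    fitness the fireworks optimizer minimizes."""
    X = _as_data(data)
    if K > X.shape[0]:
        raise ClusteringError(f"K={K} exceeds number of samples n={X.shape[0]}")
    d = X.shape[1]

    def objective(position: np.ndarray) -> float:
        centers = decode_centroids(position, K, d)
        return sse_loss(X, centers, assign_points(X, centers))

    return objective


def fwa_kmeans(
    data,
    K: int,
    fwa_config: FWAConfig | None = None,
    kmeans_config: KMeansConfig | None = None,
) -> ClusteringResult:
    """The hybrid method: fireworks search for a low-SSE centroid set, then
    K-means refinement from the best firework found.

    Each firework encodes all K centers as one flat vector; its fitness is the
    SSE of the decoded centroid set.  The best firework after the configured
    number of generations is decoded into the K initial centers of a standard
    K-means run, so the final loss never exceeds the best firework's fitness.
    """
    X = _as_data(data)
    if fwa_config is None:
        fwa_config = FWAConfig()
    if kmeans_config is None:
        kmeans_config = KMeansConfig(K=K, seed=fwa_config.seed)
    if kmeans_config.K != K:
        raise ClusteringError(f"kmeans_config.K={kmeans_config.K} != K={K}")
    bounds = centroid_search_bounds(X, K)
    cfg = replace(fwa_config, bounds=bounds.tolist())
    fwa_result = fwa_minimize(clustering_objective(X, K), cfg)
    init = decode_centroids(fwa_result.best_position, K, X.shape[1])
    return kmeans(X, kmeans_config, init)


def _restricted_growth_strings(n: int, K: int) -> Iterator[np.ndarray]:
    """All partitions of n items into at most K non-empty blocks, in canonical
    (restricted-growth) labeling."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_used: int) -> Iterator[np.ndarray]:
        if i == n:
            yield labels.copy()
            return
        for v in range(min(max_used + 1, K - 1) + 1):
            labels[i] = v
            yield from rec(i + 1, max(max_used, v))

    yield from rec(1, 0)


def _n_partitions(n: int, K: int) -> int:
    # Stirling numbers of the second kind, summed over 1..K blocks
    S = np.zeros((n + 1, K + 1), dtype=object)
    S[0, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, min(i, K) + 1):
            S[i, j] = j * S[i - 1, j] + S[i - 1, j - 1]
    return int(sum(S[n, j] for j in range(1, K + 1)))


def exhaustive_optimal_partition(data, K: int) -> Tuple[np.ndarray, float]:
    """Brute-force SSE-optimal partition into at most K blocks.

    Enumerates every set partition, scores each with centroids at block means,
    and returns the labeling and loss of the minimum.  Refuses instances with
    more than ``MAX_ORACLE_PARTITIONS`` partitions.
    """
    X = _as_data(data)
    n = X.shape[0]
    K = min(K, n)
    total = _n_partitions(n, K)
    if total > MAX_ORACLE_PARTITIONS:
        raise ClusteringError(
            f"instance too large for exhaustive search: {total} partitions "
            f"exceeds the cap of {MAX_ORACLE_PARTITIONS}"
        )
    best_labels = None
    best_loss = np.inf
    for labels in _restricted_growth_strings(n, K):
        loss = 0.0
        for k in range(labels.max() + 1):
            block = X[labels == k]
            loss += float(np.sum((block - block.mean(axis=0)) ** 2))
        if loss < best_loss:
            best_loss = loss
            best_labels = labels
    return best_labels, best_loss
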