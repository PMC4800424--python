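"""k-means clustering of stage profiles with city-block (L1) distance.

Rows are per-row max-normalized (the heatmap convention) before clustering.
Because the L1 cost is minimized coordinate-wise by the median, the Lloyd
update uses the element-wise median centroid; initialization samples k
distinct rows with a seeded generator and the best of ``n_restarts`` runs by
total cost is kept, so results are fully determined by (matrix, k, seed,
n_restarts). The paper-style cluster counts are k=10 (embryonic), 8
(larval) and 9 (pupal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

STAGE_CLUSTER_COUNTS = {"embryonic": 10, "larval": 8, "pupal": 9}


@dataclass(frozen=True)
class ClusterResult:
    k: int
    assignments: np.ndarray  # (n,) cluster index per row
    centroids: np.ndarray  # (k, n_stages)
    total_cost: float
    seed: int
    n_restarts: int
    iterations_run: int


@dataclass(frozen=True)
class StageAssignment:
    specific: np.ndarray  # (n,) bool
    stage: tuple[str | None, ...]  # per-row stage label or None


def max_normalize_rows(values: np.ndarray) -> np.ndarray:
    """Divide each row by its maximum; all-zero rows stay zero."""
    values = np.asarray(values, dtype=float)
    maxima = values.max(axis=1, keepdims=True)
    safe = np.where(maxima > 0, maxima, 1.0)
    return values / safe


def _l1_cost(X: np.ndarray, centroids: np.ndarray, assignments: np.ndarray) -> float:
    return float(np.abs(X - centroids[assignments]).sum())


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float):
    n = len(X)
    init = rng.choice(n, size=k, replace=False)
    centroids = X[init].copy()
    assignments = np.argmin(cdist(X, centroids, metric="cityblock"), axis=1)
    prev_cost = _l1_cost(X, centroids, assignments)
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        for c in range(k):
            members = X[assignments == c]
            if len(members):
                centroids[c] = np.median(members, axis=0)
        dists = cdist(X, centroids, metric="cityblock")
        assignments = np.argmin(dists, axis=1)
        # re-seed empty clusters with the row currently farthest from its centroid
        for c in range(k):
            if not (assignments == c).any():
                far = int(np.argmax(dists[np.arange(n), assignments]))
                centroids[c] = X[far]
                dists = cdist(X, centroids, metric="cityblock")
                assignments = np.argmin(dists, axis=1)
        cost = _l1_cost(X, centroids, assignments)
        if cost > prev_cost + 1e-9:
            raise AssertionError("L1 cost increased during Lloyd iteration")
        if prev_cost - cost < tol:
            prev_cost = cost
            break
        prev_cost = cost
    return assignments, centroids, prev_cost, iterations


def kmeans_cityblock(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterResult:
    """Best-of-restarts Lloyd k-means under city-block distance."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if not np.isfinite(X).all():
        raise ValueError("profiles must be finite")
    if k < 1 or k > len(X):
        raise ValueError(f"k={k} must lie in [1, {len(X)}]")
    best = None
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    for restart, child in enumerate(children):
        rng = np.random.default_rng(child)
        assignments, centroids, cost, iterations = _lloyd(X, k, rng, max_iter, tol)
        if best is None or cost < best[2] - 1e-12:
            best = (assignments, centroids, cost, iterations)
    assignments, centroids, cost, iterations = best
    return ClusterResult(
        k=k,
        assignments=assignments,
        centroids=centroids,
        total_cost=cost,
        seed=seed,
        n_restarts=n_restarts,
        iterations_run=iterations,
    )


def cluster_counts_for_stage(
    stage: str, overrides: dict[str, int] | None = None
) -> int:
    """k for a developmental super-stage: embryonic 10, larval 8, pupal 9."""
    counts = dict(STAGE_CLUSTER_COUNTS)
    if overrides:
        counts.update(overrides)
    if stage not in counts:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(counts)}")
    return counts[stage]


def _peak_stage(vector: np.ndarray) -> int:
    """Argmax with ties resolved to the earliest stage (small tolerance)."""
    best = float(vector.max())
    return int(np.argmax(vector >= best - 1e-12))


def assign_stage_specific(
    result: ClusterResult,
    stage_labels: list[str],
    dominance: float = 0.5,
) -> StageAssignment:
    """Cluster-mediated stage-specific calls.

    A cluster is stage-specific when, after row-sum normalization of its
    centroid, the peak stage holds a fraction strictly greater than
    *dominance*; members inherit the centroid's peak stage (ties to the
    earliest stage).
    """
    k = result.k
    cluster_specific = np.zeros(k, dtype=bool)
    cluster_stage: list[str | None] = [None] * k
    for c in range(k):
        centroid = result.centroids[c]
        total = centroid.sum()
        if total <= 0:
            continue
        shares = centroid / total
        peak = _peak_stage(shares)
        if shares[peak] > dominance:
            cluster_specific[c] = True
            cluster_stage[c] = stage_labels[peak]
    specific = cluster_specific[result.assignments]
    stage = tuple(
        cluster_stage[c] if cluster_specific[c] else None for c in result.assignments
    )
    return StageAssignment(specific=specific, stage=stage)


def per_row_stage_specific(
    values: np.ndarray, stage_labels: list[str], dominance: float = 0.5
) -> StageAssignment:
    """Alternative per-row mode: a row is specific when its own row-sum-normalized
    peak fraction exceeds *dominance* (no clustering involved)."""
    values = np.asarray(values, dtype=float)
    specific = np.zeros(len(values), dtype=bool)
    stage: list[str | None] = [None] * len(values)
    for i, row in enumerate(values):
        total = row.sum()
        if total <= 0:
            continue
        shares = row / total
        peak = _peak_stage(shares)
        if shares[peak] > dominance:
            specific[i] = True
            stage[i] = stage_labels[peak]
    return StageAssignment(specific=specific, stage=tuple(stage))


def heatmap_order(
    result: ClusterResult, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row order for a heatmap and the per-row max-normalized values.

    Clusters are ordered by their centroid's peak stage (ties by cluster
    index); within a cluster rows sort by descending value at that peak
    stage (ties by row index).
    """
    X = np.asarray(X, dtype=float)
    norm = max_normalize_rows(X)
    peaks = [(_peak_stage(result.centroids[c]), c) for c in range(result.k)]
    order: list[int] = []
    for peak, c in sorted(peaks):
        members = np.flatnonzero(result.assignments == c)
        members = members[np.lexsort((members, -norm[members, peak]))]
        order.extend(members.tolist())
    order_arr = np.array(order, dtype=int)
    return order_arr, norm[order_arr]
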