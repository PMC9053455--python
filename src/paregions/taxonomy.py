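"""Two-stage regional taxonomy: hierarchical exploration, then seeded K-means.

Stage one runs agglomerative clustering under several linkage rules and
distance measures and scores, for each candidate number of clusters k, how
well the resulting partitions agree across runs (mean pairwise adjusted Rand
index).  A robust k is recommended from that agreement profile.  Stage two
takes the centroids of the Ward / squared-Euclidean partition at the chosen k
as fixed seeds for Lloyd's K-means algorithm (no random restarts), and the
four final clusters are labeled semantically by which activity rate their
centroid dominates.

The agglomeration is implemented with the Lance-Williams recurrence so the
conventions are pinned down: Ward operates on squared Euclidean distances and
its recorded merge height is the *increase in total within-cluster sum of
squares* (Delta-ESS; d^2/2 when two singletons merge); the other linkages
record the plain cluster dissimilarity.  All ties break toward the lowest
cluster index, and the stage is deterministic given the input (rows are
ordered by region id internally).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .scoring import PROFILE_RATE_COLUMNS

logger = logging.getLogger(__name__)

LINKAGES = ("ward", "complete", "average", "single")
DISTANCES = ("squared_euclidean", "euclidean", "manhattan")

#: cluster label attached to the cluster whose centroid maximizes each rate
RATE_TO_LABEL = {
    "rate_non_active": "unhealthy",
    "rate_below_healthy": "below-healthy",
    "rate_healthy": "healthy",
    "rate_extra_healthy": "extra-healthy",
}

#: default exploration battery (single linkage is available but excluded from
#: the default set: its chaining behaviour makes it a poor vote at this scale)
DEFAULT_RUNS: Tuple[Tuple[str, str], ...] = (
    ("ward", "squared_euclidean"),
    ("complete", "euclidean"),
    ("average", "euclidean"),
    ("complete", "manhattan"),
    ("average", "manhattan"),
)

DEFAULT_K_RANGE = (2, 3, 4, 5, 6)


def profiles_matrix(profiles: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
    """Extract the (n, 4) rate matrix ordered by region id (tie-break anchor)."""
    ordered = profiles.sort_values("region_id").reset_index(drop=True)
    X = ordered[PROFILE_RATE_COLUMNS].to_numpy(dtype=float)
    return X, ordered["region_id"].astype(str).tolist()


def dissimilarity_matrix(X: np.ndarray, distance: str) -> np.ndarray:
    if distance == "squared_euclidean":
        return squareform(pdist(X, metric="sqeuclidean"))
    if distance == "euclidean":
        return squareform(pdist(X, metric="euclidean"))
    if distance == "manhattan":
        return squareform(pdist(X, metric="cityblock"))
    raise ValueError(f"unknown distance {distance!r}; expected one of {DISTANCES}")


@dataclass
class Dendrogram:
    """Full merge tree from one agglomerative run.

    ``merges`` lists (slot_i, slot_j, height, new_size) in merge order, where
    slots are the lowest original row index in each merged cluster and
    heights follow the convention documented in the module docstring.
    """

    n: int
    linkage: str
    distance: str
    merges: List[Tuple[int, int, float, int]]

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def cut(self, k: int) -> np.ndarray:
        """Partition into k clusters; labels are canonicalized by order of
        each cluster's smallest member index."""
        if not 1 <= k <= self.n:
            raise ValueError(f"k must be in [1, {self.n}], got {k}")
        parent = np.arange(self.n)

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j, _, _ in self.merges[: self.n - k]:
            ri, rj = find(i), find(j)
            lo, hi = min(ri, rj), max(ri, rj)
            parent[hi] = lo
        roots = np.array([find(i) for i in range(self.n)])
        _, labels = np.unique(roots, return_inverse=True)
        return labels


def agglomerate(X: np.ndarray, linkage: str, distance: str) -> Dendrogram:
    """Lance-Williams agglomeration with lowest-index-first tie-breaking."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    if linkage == "ward" and distance != "squared_euclidean":
        raise ValueError("ward linkage requires the squared_euclidean distance")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two profiles to cluster")
    D = dissimilarity_matrix(X, distance)
    np.fill_diagonal(D, np.inf)
    size = np.ones(n, dtype=int)
    active = np.ones(n, dtype=bool)
    merges: List[Tuple[int, int, float, int]] = []

    for _ in range(n - 1):
        # lowest-index-first among minimal pairs: np.argmin on the masked
        # matrix returns the first (row-major) occurrence of the minimum
        sub = np.where(np.outer(active, active), D, np.inf)
        np.fill_diagonal(sub, np.inf)
        flat = np.argmin(sub)
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        height = d_ij / 2.0 if linkage == "ward" else d_ij
        ni, nj = size[i], size[j]
        k_idx = np.flatnonzero(active & (np.arange(n) != i) & (np.arange(n) != j))
        if linkage == "single":
            new = np.minimum(D[i, k_idx], D[j, k_idx])
        elif linkage == "complete":
            new = np.maximum(D[i, k_idx], D[j, k_idx])
        elif linkage == "average":
            new = (ni * D[i, k_idx] + nj * D[j, k_idx]) / (ni + nj)
        else:  # ward on squared Euclidean
            nk = size[k_idx]
            new = ((ni + nk) * D[i, k_idx] + (nj + nk) * D[j, k_idx] - nk * d_ij) / (
                ni + nj + nk
            )
        D[i, k_idx] = new
        D[k_idx, i] = new
        size[i] = ni + nj
        active[j] = False
        merges.append((i, j, float(height), int(size[i])))
    return Dendrogram(n=n, linkage=linkage, distance=distance, merges=merges)


@dataclass
class LinkageRun:
    linkage: str
    distance: str
    dendrogram: Dendrogram
    partitions: Dict[int, np.ndarray]


@dataclass
class LinkageExploration:
    runs: List[LinkageRun]
    k_range: Tuple[int, ...]

    def agreement(self) -> pd.DataFrame:
        """Mean pairwise adjusted Rand index across runs, per candidate k."""
        if len(self.runs) < 2:
            raise ValueError("need at least two runs to measure agreement")
        rows = []
        for k in self.k_range:
            aris = [
                adjusted_rand_score(a.partitions[k], b.partitions[k])
                for a, b in itertools.combinations(self.runs, 2)
            ]
            rows.append({"k": k, "mean_ari": float(np.mean(aris))})
        return pd.DataFrame(rows)


def hierarchical_cluster(
    profiles: pd.DataFrame,
    linkage: str,
    distance: str,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
) -> LinkageRun:
    """One hierarchical run: full merge tree plus cut partitions for each k."""
    X, _ = profiles_matrix(profiles)
    dendro = agglomerate(X, linkage, distance)
    ks = tuple(k for k in k_range if 2 <= k <= len(X))
    partitions = {k: dendro.cut(k) for k in ks}
    return LinkageRun(linkage=linkage, distance=distance, dendrogram=dendro, partitions=partitions)


def explore_linkages(
    profiles: pd.DataFrame,
    runs: Sequence[Tuple[str, str]] = DEFAULT_RUNS,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
) -> LinkageExploration:
    ks = tuple(k for k in k_range if 2 <= k <= len(profiles))
    return LinkageExploration(
        runs=[hierarchical_cluster(profiles, l, d, ks) for l, d in runs],
        k_range=ks,
    )


def _height_jump(dendro: Dendrogram, k: int) -> float:
    """Relative merge-cost increase when the k-cluster partition is destroyed.

    With heights h_1 <= ... <= h_{n-1}, the k-cluster partition is formed by
    merge n-k and destroyed by merge n-k+1; the jump is their ratio.  Large
    jumps mark partitions whose clusters are far apart relative to their
    internal structure.
    """
    h = dendro.heights
    destroy = h[dendro.n - k]
    form = h[dendro.n - k - 1] if dendro.n - k - 1 >= 0 else 0.0
    if form <= 0.0:
        return np.inf if destroy > 0 else 1.0
    return float(destroy / form)


def choose_k(
    exploration: LinkageExploration, robustness_threshold: float = 0.8
) -> Tuple[Optional[int], pd.DataFrame]:
    """Recommend the number of clusters: stability screen + dendrogram elbow.

    Candidate k values whose mean pairwise ARI across runs falls below the
    robustness threshold are discarded; among the robust candidates the one
    with the largest relative merge-height jump in the Ward dendrogram (the
    first run's dendrogram when Ward is absent) is recommended.  Agreement
    alone cannot arbitrate between nested partitions -- coarser cuts of
    well-separated data agree across methods just as perfectly as the right
    one -- which is why the elbow supplies the resolution.  Returns
    ``(None, report)`` when no candidate is robust, forcing an explicit user
    choice.
    """
    report = exploration.agreement()
    ward = next((r for r in exploration.runs if r.linkage == "ward"), exploration.runs[0])
    report["height_jump"] = [
        _height_jump(ward.dendrogram, int(k)) for k in report["k"]
    ]
    eligible = report[report["mean_ari"] >= robustness_threshold]
    if eligible.empty:
        logger.warning(
            "no candidate k reaches mean ARI %.2f; no recommendation", robustness_threshold
        )
        return None, report
    k = int(eligible.loc[eligible["height_jump"].idxmax(), "k"])
    return k, report


@dataclass
class ClusterSolution:
    """Final taxonomy: region assignments, centroids and diagnostics."""

    assignments: Dict[str, int]
    centroids: np.ndarray
    k: int
    inertia: float
    seed_centroids: np.ndarray
    n_iter: int
    labels: Optional[Dict[int, str]] = None

    def label_of(self, region_id: str) -> Optional[str]:
        if self.labels is None:
            return None
        return self.labels[self.assignments[region_id]]

    def assignment_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region_id": rid,
                "cluster_index": ci,
                "cluster_label": self.labels[ci] if self.labels else "",
            }
            for rid, ci in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows)


def _inertia(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(np.sum((X - centroids[labels]) ** 2))


def kmeans_from_seeds(
    profiles: pd.DataFrame,
    seeds: np.ndarray,
    max_iter: int = 300,
) -> ClusterSolution:
    """Lloyd's algorithm from fixed seed centroids; fully deterministic.

    Assignment ties break toward the lowest centroid index; an empty cluster
    is reseeded to the point currently farthest from its assigned centroid.
    """
    X, rids = profiles_matrix(profiles)
    seeds = np.asarray(seeds, dtype=float)
    k = seeds.shape[0]
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of profiles ({len(X)})")
    if len(np.unique(seeds, axis=0)) != k:
        raise ValueError("seed centroids must be distinct")
    centroids = seeds.copy()
    labels = np.full(len(X), -1)
    prev_inertia = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)  # first minimum -> lowest index
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(d2[np.arange(len(X)), new_labels]))
                logger.info("empty cluster %d reseeded to farthest point %s", c, rids[far])
                new_labels[far] = c
        new_centroids = np.vstack([X[new_labels == c].mean(axis=0) for c in range(k)])
        cur_inertia = _inertia(X, new_centroids, new_labels)
        if cur_inertia > prev_inertia + 1e-9:
            logger.warning("inertia increased (%.6g -> %.6g); stopping", prev_inertia, cur_inertia)
            break
        converged = np.array_equal(new_labels, labels)
        labels, centroids, prev_inertia = new_labels, new_centroids, cur_inertia
        if converged:
            break
    return ClusterSolution(
        assignments={rid: int(c) for rid, c in zip(rids, labels)},
        centroids=centroids,
        k=k,
        inertia=float(prev_inertia),
        seed_centroids=seeds,
        n_iter=n_iter,
    )


def seed_centroids_from_partition(profiles: pd.DataFrame, partition: np.ndarray) -> np.ndarray:
    """Per-cluster mean profiles of a hierarchical partition (K-means seeds)."""
    X, _ = profiles_matrix(profiles)
    ks = np.unique(partition)
    return np.vstack([X[partition == c].mean(axis=0) for c in ks])


def label_clusters(solution: ClusterSolution) -> ClusterSolution:
    """Attach the four semantic labels by optimal one-to-one assignment.

    Each label goes to the cluster whose centroid is large in the matching
    rate; the bijection maximizes the summed chosen centroid components, so
    ties never produce duplicate labels.
    """
    if solution.k != 4:
        logger.warning("labeling skipped: requires k=4, got k=%d", solution.k)
        return solution
    rate_order = list(RATE_TO_LABEL.keys())  # column order of centroids
    # score[c, r] = centroid of cluster c on rate r
    score = solution.centroids
    row, col = linear_sum_assignment(-score)
    labels = {int(c): RATE_TO_LABEL[rate_order[int(r)]] for c, r in zip(row, col)}
    solution.labels = labels
    return solution


@dataclass
class TaxonomyResult:
    exploration: LinkageExploration
    agreement: pd.DataFrame
    recommended_k: Optional[int]
    k_used: int
    solution: ClusterSolution


def build_taxonomy(
    profiles: pd.DataFrame,
    runs: Sequence[Tuple[str, str]] = DEFAULT_RUNS,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    k_override: Optional[int] = None,
    robustness_threshold: float = 0.8,
    max_iter: int = 300,
) -> TaxonomyResult:
    """Full taxonomy stage: explore, choose k, seed K-means with the Ward
    centroids, refine, and (when k=4) label the clusters."""
    exploration = explore_linkages(profiles, runs, k_range)
    recommended, agreement = choose_k(exploration, robustness_threshold)
    k = k_override if k_override is not None else recommended
    if k is None:
        raise ValueError(
            "no robust cluster count found and no override supplied; "
            "inspect the agreement report and pass k explicitly"
        )
    ward_run = next(
        (r for r in exploration.runs if r.linkage == "ward"), None
    )
    if ward_run is None:
        ward_run = hierarchical_cluster(profiles, "ward", "squared_euclidean", [k])
    partition = ward_run.partitions.get(k, ward_run.dendrogram.cut(k))
    seeds = seed_centroids_from_partition(profiles, partition)
    solution = kmeans_from_seeds(profiles, seeds, max_iter=max_iter)
    solution = label_clusters(solution)
    return TaxonomyResult(
        exploration=exploration,
        agreement=agreement,
        recommended_k=recommended,
        k_used=k,
        solution=solution,
    )
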