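"""Conformational clustering of trajectory frames from a pairwise RMSD matrix.

Agglomerative Ward clustering over the frame × frame RMSD matrix with
automatic cluster-count selection by the elbow rule on the within-cluster
dispersion curve. Ward's objective formally assumes Euclidean distances; the
RMSD matrix is fed to it in the standard distance-as-if-Euclidean sense, an
approximation inherited from common trajectory-clustering practice and noted
here rather than hidden.

A deterministic k-medoids (PAM BUILD + SWAP) alternative is provided for
comparison; the hierarchical route is the default because it is deterministic
and needs nothing beyond the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError

__all__ = [
    "Linkage",
    "ClusterAssignment",
    "ward_linkage",
    "select_k_elbow",
    "cut_clusters",
    "dispersion_curve",
    "kmedoids",
]


@dataclass(frozen=True)
class Linkage:
    """Agglomerative merge table: (cluster_i, cluster_j, height Å, size) rows."""

    merges: np.ndarray  # scipy linkage format, (n-1, 4)
    n_frames: int

    def __post_init__(self) -> None:
        if self.merges.shape != (self.n_frames - 1, 4):
            raise ValidationError("linkage must have n_frames - 1 merge rows")


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-frame cluster labels in 1..k with per-cluster medoid frames."""

    labels: np.ndarray  # (n_frames,), ints in 1..k
    k: int
    component: str
    medoids: np.ndarray  # (k,), frame index of each cluster's medoid
    frame_indices: np.ndarray  # frame universe the labels refer to

    def __post_init__(self) -> None:
        if set(np.unique(self.labels)) != set(range(1, self.k + 1)):
            raise ValidationError("labels must cover exactly 1..k")
        for c in range(1, self.k + 1):
            if self.labels[self.medoids[c - 1]] != c:
                raise ValidationError(f"medoid of cluster {c} is not in that cluster")

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def cluster_frames(self, c: int) -> np.ndarray:
        """Frame indices (within the frame universe) belonging to cluster c."""
        return self.frame_indices[self.labels == c]


def _validate_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] < 2:
        raise ValidationError("matrix must be square with at least 2 frames")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValidationError("matrix must be symmetric")
    if np.any(m < 0):
        raise ValidationError("matrix must be non-negative")
    if not np.allclose(np.diag(m), 0.0, atol=1e-10):
        raise ValidationError("matrix diagonal must be zero")
    return m


def ward_linkage(matrix: np.ndarray) -> Linkage:
    """Ward agglomeration of the pairwise distance matrix (variance-minimizing merges)."""
    m = _validate_matrix(matrix)
    condensed = squareform(m, checks=False)
    merges = _scipy_linkage(condensed, method="ward")
    return Linkage(merges=merges, n_frames=m.shape[0])


def _medoid(matrix: np.ndarray, members: np.ndarray) -> int:
    """Frame minimizing summed intra-cluster distance; ties → lowest frame index."""
    sums = matrix[np.ix_(members, members)].sum(axis=1)
    return int(members[int(np.argmin(sums))])  # argmin takes the first minimum


def dispersion_curve(matrix: np.ndarray, linkage: Linkage, k_max: int) -> np.ndarray:
    """W(k) for k = 1..k_max: sum over clusters of the mean squared distance
    of members to the cluster medoid, read off the distance matrix."""
    m = _validate_matrix(matrix)
    W = np.empty(k_max)
    for k in range(1, k_max + 1):
        labels = fcluster(linkage.merges, t=k, criterion="maxclust")
        total = 0.0
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            med = _medoid(m, members)
            total += float(np.mean(m[members, med] ** 2))
        W[k - 1] = total
    return W


def select_k_elbow(matrix: np.ndarray, linkage: Linkage, k_max: int) -> int:
    """Elbow rule on the dispersion curve.

    Returns the k whose point (k, W(k)) lies farthest (perpendicular
    distance) from the chord through (1, W(1)) and (k_max, W(k_max)); ties go
    to the smallest k. A flat curve (all frames identical) yields k = 1.
    """
    n = linkage.n_frames
    if not (2 <= k_max < n):
        raise ValidationError(f"k_max must satisfy 2 <= k_max < n_frames; got {k_max} (n={n})")
    W = dispersion_curve(matrix, linkage, k_max)
    ks = np.arange(1, k_max + 1, dtype=float)
    p1 = np.array([1.0, W[0]])
    p2 = np.array([float(k_max), W[-1]])
    chord = p2 - p1
    norm = np.hypot(*chord)
    if norm == 0.0:
        return 1
    # scale W to the chord's aspect so the rule is unit-insensitive
    pts = np.stack([ks, W], axis=1) - p1
    dists = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    return int(np.argmax(dists)) + 1  # first maximum → smallest k on ties


def cut_clusters(linkage: Linkage, k: int, matrix: np.ndarray, component: str = "") -> ClusterAssignment:
    """Cut the dendrogram into k clusters.

    Labels are renumbered by order of first appearance along the trajectory;
    each cluster's medoid minimizes the summed intra-cluster distance (ties →
    lowest frame index).
    """
    if not (1 <= k <= linkage.n_frames):
        raise ValidationError(f"k must be in 1..n_frames; got {k}")
    m = _validate_matrix(matrix)
    raw = fcluster(linkage.merges, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    k_eff = len(remap)
    medoids = np.array([_medoid(m, np.flatnonzero(labels == c)) for c in range(1, k_eff + 1)])
    return ClusterAssignment(
        labels=labels,
        k=k_eff,
        component=component,
        medoids=medoids,
        frame_indices=np.arange(len(labels)),
    )


def kmedoids(matrix: np.ndarray, k: int, component: str = "") -> ClusterAssignment:
    """Deterministic k-medoids (PAM BUILD + SWAP) directly on the matrix.

    Provided as a cross-check on the hierarchical route; both operate on the
    same pairwise RMSD matrix.
    """
    m = _validate_matrix(matrix)
    n = m.shape[0]
    if not (1 <= k <= n):
        raise ValidationError(f"k must be in 1..n_frames; got {k}")
    # BUILD: greedily add the medoid that most reduces total cost.
    medoids: list[int] = [int(np.argmin(m.sum(axis=1)))]
    while len(medoids) < k:
        current = m[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - m, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    # SWAP: steepest-descent swaps until no improvement.
    improved = True
    while improved:
        improved = False
        cost = m[:, medoids].min(axis=1).sum()
        best = (0.0, None, None)
        for mi, med in enumerate(medoids):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = cand
                delta = cost - m[:, trial].min(axis=1).sum()
                if delta > best[0] + 1e-12:
                    best = (delta, mi, cand)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            improved = True
    medoids_arr = np.array(sorted(medoids))
    raw = np.argmin(m[:, medoids_arr], axis=1)
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    k_eff = len(remap)
    meds = np.array([_medoid(m, np.flatnonzero(labels == c)) for c in range(1, k_eff + 1)])
    return ClusterAssignment(
        labels=labels, k=k_eff, component=component, medoids=meds, frame_indices=np.arange(n)
    )
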