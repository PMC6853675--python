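"""Tanimoto similarity, two-medoids (PAM) clustering and dissimilarity
summaries.

The Tanimoto (Jaccard) coefficient |A∩B|/|A∪B| over set bits is a
similarity; 1 − Tanimoto is the Jaccard distance, a true metric, and is
used wherever a distance is required.  Two-medoids clustering asks whether
unsupervised structure splits a dataset into chemically homogeneous halves;
the dissimilarity summary compares that against supervised splits such as
the top-activity decile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datasets import FingerprintMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "tanimoto",
    "pairwise_distance_matrix",
    "MedoidClustering",
    "two_medoids",
    "DissimilaritySummary",
    "dissimilarity_summary",
]


def tanimoto(x1: np.ndarray, x2: np.ndarray) -> float:
    """Tanimoto similarity of two binary vectors: |x1 & x2| / |x1 | x2|.

    Two all-zero vectors are identical empty substructure sets and return 1
    by convention (logged).
    """
    a = np.asarray(x1)
    b = np.asarray(x2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fingerprints must be equal-length vectors")
    union = int(np.maximum(a, b).sum())
    if union == 0:
        logger.info("tanimoto of two all-zero fingerprints; returning 1")
        return 1.0
    return float((a * b).sum()) / union


def pairwise_distance_matrix(fps: FingerprintMatrix) -> np.ndarray:
    """Symmetric N x N Jaccard distance matrix, d_ij = 1 - tanimoto(x_i, x_j)."""
    if fps.n_molecules < 2:
        raise ValueError("need at least 2 fingerprints")
    if (fps.bits.sum(axis=1) == 0).any():
        rows = np.flatnonzero(fps.bits.sum(axis=1) == 0)
        raise ValueError(
            f"all-zero fingerprints at rows {rows[:5].tolist()}; no valid "
            "molecule maps to the empty substructure set"
        )
    return squareform(pdist(fps.bits.astype(bool), metric="jaccard"))


@dataclass(frozen=True)
class MedoidClustering:
    """A two-medoids assignment with its within/global distance summaries."""

    medoid_indices: tuple[int, int]
    assignment: np.ndarray
    within_cluster_mean_distance: tuple[float, float]
    global_mean_distance: float
    total_cost: float
    converged: bool


def _assign(distances: np.ndarray, medoids: tuple[int, int]) -> np.ndarray:
    d0 = distances[:, medoids[0]]
    d1 = distances[:, medoids[1]]
    return (d1 < d0).astype(int)  # ties go to cluster 0


def _cost(distances: np.ndarray, medoids: tuple[int, int]) -> float:
    return float(np.minimum(distances[:, medoids[0]], distances[:, medoids[1]]).sum())


def two_medoids(
    distances: np.ndarray, seed: int = 0, max_iter: int = 100
) -> MedoidClustering:
    """Partition-around-medoids with k = 2 on a precomputed distance matrix.

    BUILD picks the point of least total distance as the first medoid and
    the point whose addition most reduces total cost as the second; SWAP
    then greedily applies the best (medoid, non-medoid) exchange until the
    total within-cluster distance to the medoids stops decreasing or
    ``max_iter`` sweeps elapse (a warning is logged on non-convergence).
    Deterministic: remaining ties are broken by lowest index.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distances must be a square matrix")
    if n < 4:
        raise ValueError(f"need at least 4 points to split into 2 clusters, got {n}")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distances must be symmetric with zero diagonal")

    # BUILD
    m0 = int(np.argmin(d.sum(axis=0)))
    best_m1, best_cost = None, np.inf
    for j in range(n):
        if j == m0:
            continue
        c = _cost(d, (m0, j))
        if c < best_cost:
            best_m1, best_cost = j, c
    medoids = (m0, int(best_m1))
    cost = best_cost

    # SWAP: best-improvement exchanges
    converged = False
    for _ in range(max_iter):
        best_swap, best_swap_cost = None, cost
        for slot in (0, 1):
            other = medoids[1 - slot]
            for j in range(n):
                if j in medoids:
                    continue
                trial = (j, other) if slot == 0 else (other, j)
                c = _cost(d, trial)
                if c < best_swap_cost - 1e-12:
                    best_swap, best_swap_cost = trial, c
        if best_swap is None:
            converged = True
            break
        medoids, cost = best_swap, best_swap_cost
    if not converged:
        logger.warning("two_medoids did not converge in %d sweeps", max_iter)

    medoids = (min(medoids), max(medoids))
    assignment = _assign(d, medoids)
    # medoids always belong to their own cluster
    assignment[medoids[0]] = 0
    assignment[medoids[1]] = 1
    within = []
    for c in (0, 1):
        members = np.flatnonzero(assignment == c)
        within.append(_mean_pairwise(d, members) if members.size >= 2 else 0.0)
    iu = np.triu_indices(n, k=1)
    return MedoidClustering(
        medoid_indices=medoids,
        assignment=assignment,
        within_cluster_mean_distance=(within[0], within[1]),
        global_mean_distance=float(d[iu].mean()),
        total_cost=cost,
        converged=converged,
    )


def _mean_pairwise(d: np.ndarray, idx: np.ndarray) -> float:
    sub = d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


@dataclass(frozen=True)
class DissimilaritySummary:
    """Mean pairwise distance within a subset vs the whole dataset."""

    subset_mean_pairwise: float
    global_mean_pairwise: float

    @property
    def relative_reduction(self) -> float:
        """1 - subset/global: how much more self-similar the subset is."""
        return 1.0 - self.subset_mean_pairwise / self.global_mean_pairwise


def dissimilarity_summary(
    distances: np.ndarray, subset: np.ndarray
) -> DissimilaritySummary:
    """Compare within-subset to global mean pairwise distance.

    Means run over unordered distinct pairs only.  A subset of mutually
    similar molecules in a diverse pool yields a large relative reduction.
    """
    d = np.asarray(distances, dtype=float)
    idx = np.asarray(subset, dtype=int)
    if len(set(idx.tolist())) != idx.size:
        raise ValueError("subset indices must be distinct")
    if idx.size < 2:
        raise ValueError("subset must contain at least 2 molecules")
    iu = np.triu_indices(d.shape[0], k=1)
    return DissimilaritySummary(
        subset_mean_pairwise=_mean_pairwise(d, idx),
        global_mean_pairwise=float(d[iu].mean()),
    )
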