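"""Resampling-based consensus k-means and hierarchical partitioning.

The consensus matrix M holds, for every pair of subjects, the empirical
probability of landing in the same k-means cluster across many random
subsamples of the cohort: ``M_nq = Q_nq / I_nq`` where Q counts same-cluster
co-assignments and I counts co-selections.  Cluster membership is then read
off by cutting an agglomerative tree built on ``1 - M``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

logger = logging.getLogger("phenoclust")


@dataclass
class ConsensusMatrix:
    """Pairwise same-cluster probabilities with their co-assignment counts."""

    M: np.ndarray
    Q: np.ndarray | None = None
    I: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.M.shape[0]

    def distance(self) -> np.ndarray:
        D = 1.0 - self.M
        np.fill_diagonal(D, 0.0)
        return D


@dataclass
class ClusterSolution:
    """1-based cluster labels, renumbered so cluster 1 is the largest."""

    labels: np.ndarray
    K: int
    sizes: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sizes == 0):
            raise ValueError("empty cluster in solution")
        if int(self.sizes.sum()) != len(self.labels):
            raise ValueError("cluster sizes do not sum to N")


def _renumber_by_size(raw: np.ndarray) -> ClusterSolution:
    ids, counts = np.unique(raw, return_counts=True)
    # decreasing size, ties by first appearance
    first = np.array([np.argmax(raw == i) for i in ids])
    order = np.lexsort((first, -counts))
    mapping = {int(ids[o]): rank + 1 for rank, o in enumerate(order)}
    labels = np.array([mapping[int(x)] for x in raw], dtype=int)
    sizes = np.array([int((labels == k).sum()) for k in range(1, len(ids) + 1)])
    return ClusterSolution(labels=labels, K=len(ids), sizes=sizes)


def consensus_matrix(
    V: np.ndarray,
    K: int,
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    replicates: int = 8,
    seed: int | np.random.SeedSequence | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ConsensusMatrix:
    """Consensus matrix from repeated k-means on random subsamples.

    Each resample draws ``subsample_fraction`` of the subjects without
    replacement and partitions them with k-means (k-means++ starts, best of
    ``replicates`` restarts by inertia).  Per-resample RNG streams are derived
    from ``seed`` up front, so the result does not depend on execution order.
    """
    V = np.asarray(V, dtype=float)
    N = V.shape[0]
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > N:
        raise ValueError(f"K={K} exceeds the number of subjects ({N})")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    n_sub = max(K, int(round(subsample_fraction * N)))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_resamples)
    Q = np.zeros((N, N), dtype=np.int64)
    I = np.zeros((N, N), dtype=np.int64)
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.choice(N, size=n_sub, replace=False)
        km = KMeans(
            n_clusters=K,
            n_init=replicates,
            init="k-means++",
            max_iter=max_iter,
            tol=tol,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(V[idx])
        I[np.ix_(idx, idx)] += 1
        for c in range(K):
            members = idx[km.labels_ == c]
            Q[np.ix_(members, members)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(I > 0, Q / np.maximum(I, 1), np.nan)
    undefined = np.isnan(M)
    np.fill_diagonal(undefined, False)
    if undefined.any():
        off = ~np.eye(N, dtype=bool) & ~undefined
        grand = float(M[off].mean()) if off.any() else 0.0
        logger.warning(
            "%d subject pairs never co-selected in %d resamples; "
            "filling with grand mean %.4f", int(undefined.sum() // 2), n_resamples, grand,
        )
        M[undefined] = grand
    np.fill_diagonal(M, 1.0)
    M = (M + M.T) / 2.0
    return ConsensusMatrix(
        M=M, Q=Q, I=I,
        params={
            "K": K,
            "n_resamples": n_resamples,
            "subsample_fraction": subsample_fraction,
            "replicates": replicates,
        },
    )


def average_consensus(matrices: list[ConsensusMatrix]) -> ConsensusMatrix:
    """Elementwise mean of consensus matrices over imputed datasets."""
    if not matrices:
        raise ValueError("no consensus matrices to average")
    n = matrices[0].n
    for cm in matrices:
        if cm.n != n:
            raise ValueError("consensus matrices have mismatched shapes")
    M = np.mean([cm.M for cm in matrices], axis=0)
    np.fill_diagonal(M, 1.0)
    Q = sum(cm.Q for cm in matrices) if all(cm.Q is not None for cm in matrices) else None
    I = sum(cm.I for cm in matrices) if all(cm.I is not None for cm in matrices) else None
    return ConsensusMatrix(M=M, Q=Q, I=I, params=dict(matrices[0].params, averaged=len(matrices)))


def hierarchical_partition(distance: np.ndarray, K: int,
                           linkage: str = "average") -> ClusterSolution:
    """Cut an agglomerative tree on a pairwise distance matrix into K groups."""
    D = np.asarray(distance, dtype=float)
    N = D.shape[0]
    if K > N:
        raise ValueError(f"K={K} exceeds the number of subjects ({N})")
    if K == N:
        return _renumber_by_size(np.arange(N))
    condensed = squareform((D + D.T) / 2.0, checks=False)
    Z = scipy_linkage(condensed, method=linkage)
    raw = fcluster(Z, t=K, criterion="maxclust")
    got = len(np.unique(raw))
    if got != K:
        logger.warning("maxclust cut yielded %d clusters instead of %d (tied merges)", got, K)
    return _renumber_by_size(raw)


__all__ = [
    "ConsensusMatrix",
    "ClusterSolution",
    "consensus_matrix",
    "average_consensus",
    "hierarchical_partition",
]
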