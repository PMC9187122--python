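"""Fusion of continuous and categorical distances, and semi-supervised refinement.

Fusion combines the consensus-based continuous distance ``1 - M`` and the
weighted Tanimoto categorical distance ``1 - T`` as a weighted
root-mean-square,

    ``D_nq = sqrt(((1 - M_nq)^2 + mu^2 (1 - T_nq)^2) / (1 + mu^2))``,

which stays in [0, 1].  The channel weight ``mu`` defaults to the ratio of the
summed redundancy weights of the categorical and continuous variables — the
ratio of *non-redundant* variable counts.

Refinement folds in an extra data domain observed only on a subset of
subjects (e.g. diary measurements): for pairs fully inside the subset the
fused distance is shifted by ``rho * (BD_nq - mean(BD))``, where BD is the
pairwise distance recomputed with the extra variables included, and clipped
at zero.  Pairs with an unobserved member are left untouched — their unknown
extra-domain distance is taken equal to the subset mean, which zeroes the
shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusMatrix
from .tanimoto import TanimotoDistance

logger = logging.getLogger("phenoclust")


@dataclass
class FusedDistance:
    D: np.ndarray
    mu: float


@dataclass
class RefinedDistance:
    G: np.ndarray
    rho: float
    subset_idx: np.ndarray
    mBD: float
    n_clipped: int = 0


def compute_mu(cont_weights: np.ndarray, cat_weights: np.ndarray) -> float:
    """Channel weight: ratio of summed categorical to continuous redundancy weights."""
    cont = np.asarray(cont_weights, dtype=float)
    cat = np.asarray(cat_weights, dtype=float)
    if cont.size == 0 or cat.size == 0:
        raise ValueError("both weight sets must be nonempty")
    denom = float(cont.sum())
    if denom == 0:
        raise ValueError("continuous weights sum to zero")
    return float(cat.sum()) / denom


def fuse(M: ConsensusMatrix | np.ndarray,
         Tdist: TanimotoDistance | np.ndarray,
         mu: float) -> FusedDistance:
    """Weighted RMS combination of continuous and categorical distances."""
    Mv = M.M if isinstance(M, ConsensusMatrix) else np.asarray(M, dtype=float)
    Tv = Tdist.D if isinstance(Tdist, TanimotoDistance) else np.asarray(Tdist, dtype=float)
    if Mv.shape != Tv.shape:
        raise ValueError("consensus and Tanimoto matrices have mismatched shapes")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    Dc = 1.0 - Mv
    D = np.sqrt((Dc ** 2 + mu ** 2 * Tv ** 2) / (1.0 + mu ** 2))
    np.fill_diagonal(D, 0.0)
    return FusedDistance(D=np.clip(D, 0.0, 1.0), mu=float(mu))


def subset_distance(V_subset: np.ndarray, K: int,
                    n_resamples: int = 1000,
                    subsample_fraction: float = 0.8,
                    replicates: int = 8,
                    seed: int | np.random.SeedSequence | None = None) -> np.ndarray:
    """Extra-domain pairwise distance BD = 1 - M over the fully observed subset.

    ``V_subset`` is the subset's normalized continuous matrix with the extra
    variables appended; the consensus run mirrors the main one at the same K.
    """
    from .consensus import consensus_matrix

    V_subset = np.asarray(V_subset, dtype=float)
    if len(V_subset) < 2 * K:
        raise ValueError(
            f"subset of {len(V_subset)} subjects too small for K={K} (need >= {2 * K})"
        )
    cm = consensus_matrix(V_subset, K=K, n_resamples=n_resamples,
                          subsample_fraction=subsample_fraction,
                          replicates=replicates, seed=seed)
    return cm.distance()


def refine(D: FusedDistance | np.ndarray,
           BD: np.ndarray,
           subset_idx: np.ndarray,
           rho: float) -> RefinedDistance:
    """Shift subset-internal distances by the centered extra-domain distance.

    ``G_nq = max(D_nq + rho * (BD_nq - mBD), 0)`` for pairs fully inside the
    subset; ``G_nq = D_nq`` otherwise.  ``mBD`` is the mean off-diagonal BD.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    Dv = D.D if isinstance(D, FusedDistance) else np.asarray(D, dtype=float)
    BD = np.asarray(BD, dtype=float)
    subset_idx = np.asarray(subset_idx, dtype=int)
    if BD.shape != (len(subset_idx), len(subset_idx)):
        raise ValueError("BD must be square over the subset")
    off = ~np.eye(len(subset_idx), dtype=bool)
    mBD = float(BD[off].mean()) if off.any() else 0.0
    G = Dv.copy()
    block = Dv[np.ix_(subset_idx, subset_idx)] + rho * (BD - mBD)
    n_clipped = int((block[off] < 0).sum()) // 2
    block = np.maximum(block, 0.0)
    G[np.ix_(subset_idx, subset_idx)] = block
    np.fill_diagonal(G, 0.0)
    return RefinedDistance(G=G, rho=float(rho), subset_idx=subset_idx,
                           mBD=mBD, n_clipped=n_clipped)


__all__ = ["FusedDistance", "RefinedDistance", "compute_mu", "fuse",
           "subset_distance", "refine"]
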