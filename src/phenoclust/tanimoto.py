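"""Tanimoto and weighted Tanimoto distances for binary indicator profiles.

Tanimoto similarity counts common "ones" but not common "zeros":
``T = sum(a_j b_j) / sum(a_j + b_j - a_j b_j)`` for 0/1 vectors.  This makes
it robust to how a categorical variable is split into indicators — two
blue-eyed subjects score the same whether or not "hazel eyes" is on the list
of options.

The weighted variant multiplies each indicator's contribution by
``w_j^2 * erf(gamma_j)^2`` where ``w_j`` is the redundancy weight and
``gamma_j`` the case/control relevance, so irrelevant indicators
(gamma_j = 0) drop out entirely and no indicator can carry weight above one.

``kprototype_phi`` is the categorical centroid distance used by k-prototype
clustering, kept as a documented reference operation only; the pipeline
itself uses the Tanimoto route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import CategoricalWeights

logger = logging.getLogger("phenoclust")


@dataclass
class BinaryDesign:
    """Subjects x indicators 0/1 matrix with per-indicator weights."""

    X: np.ndarray
    weights: CategoricalWeights | None = None
    redundancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if np.isnan(self.X).any():
            raise ValueError("binary design contains missing values; impute first")
        if not np.isin(self.X, (0.0, 1.0)).all():
            raise ValueError("binary design entries must be 0/1")

    def effective_weights(self) -> np.ndarray:
        """Per-indicator squared factor w_j^2 * erf(gamma_j)^2."""
        m = self.X.shape[1]
        w = np.ones(m) if self.redundancy is None else np.asarray(self.redundancy, float)
        if self.weights is not None and self.weights.w is not None and self.redundancy is None:
            w = np.asarray(self.weights.w, dtype=float)
        e = np.ones(m) if self.weights is None else np.asarray(self.weights.erf_weight, float)
        if len(w) != m or len(e) != m:
            raise ValueError("weight vectors do not match the number of indicators")
        return (w ** 2) * (e ** 2)


@dataclass
class TanimotoDistance:
    """Pairwise categorical distance 1 - T (zero diagonal, entries in [0, 1])."""

    D: np.ndarray


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Tanimoto similarity of two 0/1 vectors (1.0 if both all-zero)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    num = float(np.sum(a * b))
    den = float(np.sum(a + b - a * b))
    if den == 0.0:
        return 1.0
    return num / den


def weighted_tanimoto_matrix(design: BinaryDesign | np.ndarray,
                             weights: CategoricalWeights | None = None,
                             redundancy: np.ndarray | None = None) -> TanimotoDistance:
    """Pairwise weighted Tanimoto distance matrix over all subjects.

    Fully vectorized; the result is independent of pair evaluation order.
    Pairs whose profiles are both all-zero on the weighted support get
    similarity 1 (identical observed profiles), logged when it occurs.
    """
    if not isinstance(design, BinaryDesign):
        design = BinaryDesign(np.asarray(design), weights=weights, redundancy=redundancy)
    u = design.effective_weights()
    if np.all(u == 0):
        raise ValueError("all categorical weights are zero; no informative indicator")
    X = design.X
    Xu = X * u
    num = Xu @ X.T                       # sum_j a b u_j  (X binary: X^2 = X)
    s = X @ u                            # sum_j a^2 u_j per subject
    den = s[:, None] + s[None, :] - num
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(den > 0, num / np.maximum(den, np.finfo(float).tiny), 1.0)
    offdiag = ~np.eye(len(X), dtype=bool)
    n_zero = int((den[offdiag] <= 0).sum()) // 2
    if n_zero > 0:
        logger.info("%d subject pairs share an all-zero weighted profile; distance set to 0",
                    n_zero)
    D = 1.0 - T
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    return TanimotoDistance(D=D)


def kprototype_phi(cluster_size: int, matching_count: int, is_match: bool) -> float:
    """k-prototype categorical distance from a cluster centroid (reference only).

    1 for a mismatching attribute value; ``1 - C_kjr / C_k`` for a matching one,
    where ``C_kjr`` of the ``C_k`` cluster members share the value.
    """
    if cluster_size <= 0:
        raise ValueError("cluster_size must be positive")
    if not 0 <= matching_count <= cluster_size:
        raise ValueError("matching_count out of range [0, cluster_size]")
    if not is_match:
        return 1.0
    return 1.0 - matching_count / cluster_size


__all__ = ["BinaryDesign", "TanimotoDistance", "tanimoto",
           "weighted_tanimoto_matrix", "kprototype_phi"]
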