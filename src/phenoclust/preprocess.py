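"""Preprocessing for mixed clinical data prior to consensus clustering.

The stages, in pipeline order:

1.  Multiple imputation (pluggable; a seeded chained-regression default).
2.  Control-referenced scaling of continuous variables,
    ``S_in = (A_in - mean_C) / sd_C`` — standardizing by the mean and SD of a
    *reference* (non-diseased) population rather than the cohort, so that
    subtype-driven multimodality is not shrunk the way cohort z-scores would.
3.  Redundancy weighting, ``w_i = 1 / (1 + c_i / c_bar)`` with ``c_i`` the
    mean absolute Pearson correlation of variable i with all others and
    ``c_bar`` the grand mean: the least correlated (least redundant) variable
    receives the largest weight.
4.  Per-subject row normalization to unit weighted Euclidean length, so
    clustering is driven by the *direction* of a subject's profile rather
    than overall severity.
5.  Relevance weights for binary indicators,
    ``gamma_j = |ln(F_j / F_jC)|`` squashed through ``erf``, comparing case
    and control frequencies so indicators equally prevalent in cases and
    controls drop out of the categorical distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .io import CATEGORICAL, CONTINUOUS, CohortTable, VariableMeta

logger = logging.getLogger("phenoclust")


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------

def _default_imputer(values: pd.DataFrame, meta: Sequence[VariableMeta],
                     rng: np.random.Generator) -> pd.DataFrame:
    """One stochastic completion of ``values``.

    Continuous columns: two sweeps of chained linear regression on all other
    (current-guess) columns, adding Gaussian noise at the residual SD.
    Categorical columns: draws from the observed empirical distribution.
    """
    out = values.copy()
    cont = [m.name for m in meta if m.var_type == CONTINUOUS]
    # initial fill: column mean / empirical draw
    for m in meta:
        col = out[m.name]
        miss = col.isna()
        if not miss.any():
            continue
        obs = col.dropna()
        if m.var_type == CONTINUOUS:
            out.loc[miss, m.name] = float(obs.mean())
        else:
            out.loc[miss, m.name] = rng.choice(obs.to_numpy(), size=int(miss.sum()))
    # chained regression sweeps for continuous columns
    X_all = out[cont].to_numpy(dtype=float) if cont else None
    for _sweep in range(2):
        for j, name in enumerate(cont):
            miss = values[name].isna().to_numpy()
            if not miss.any():
                continue
            y = values[name].to_numpy(dtype=float)
            others = np.delete(X_all, j, axis=1)
            A = np.column_stack([np.ones(len(out)), others])
            obs = ~miss
            coef, *_ = np.linalg.lstsq(A[obs], y[obs], rcond=None)
            resid = y[obs] - A[obs] @ coef
            sd = float(np.std(resid)) if len(resid) > 1 else 0.0
            pred = A[miss] @ coef + rng.normal(0.0, sd, size=int(miss.sum()))
            X_all[miss, j] = pred
    if cont:
        out[cont] = X_all
    return out


def impute_multiple(
    table: CohortTable,
    n_imputations: int = 10,
    seed: int | None = None,
    method: Callable[[pd.DataFrame, Sequence[VariableMeta], np.random.Generator],
                     pd.DataFrame] | None = None,
) -> list[CohortTable]:
    """Produce ``n_imputations`` complete copies of ``table``.

    ``method`` may inject completions from any external imputer; it receives
    the raw values, the metadata, and a per-imputation RNG.  Columns that are
    entirely missing, or more than half missing, are rejected.
    """
    frac = table.values.isna().mean()
    entirely = frac[frac >= 1.0].index.tolist()
    if entirely:
        raise ValueError(f"columns entirely missing: {entirely}")
    heavy = frac[frac >= 0.5].index.tolist()
    if heavy:
        raise ValueError(f"columns with >=50% missing values: {heavy}")
    method = method or _default_imputer
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_imputations):
        completed = method(table.values, table.meta, np.random.default_rng(child))
        if completed.isna().any().any():
            raise ValueError("imputation method returned missing values")
        out.append(CohortTable(completed, list(table.meta)))
    return out


# ---------------------------------------------------------------------------
# control-referenced scaling
# ---------------------------------------------------------------------------

@dataclass
class StandardizedMatrix:
    """Control-scaled continuous variables S (subjects x variables)."""

    values: pd.DataFrame
    meta: list[VariableMeta]


def scale_by_controls(table: CohortTable, meta: Sequence[VariableMeta] | None = None,
                      names: Sequence[str] | None = None) -> StandardizedMatrix:
    """Scale each continuous variable by its control mean and SD."""
    meta = list(meta) if meta is not None else table.meta
    by_name = {m.name: m for m in meta}
    if names is None:
        names = [m.name for m in meta if m.var_type == CONTINUOUS]
    cols = {}
    used = []
    for name in names:
        m = by_name[name]
        if m.control_mean is None or m.control_sd is None:
            raise ValueError(f"variable {name!r} lacks control_mean/control_sd")
        if not m.control_sd > 0:
            raise ValueError(f"variable {name!r} has non-positive control_sd {m.control_sd}")
        cols[name] = (table.values[name] - m.control_mean) / m.control_sd
        used.append(m)
    return StandardizedMatrix(pd.DataFrame(cols, index=table.values.index), used)


# ---------------------------------------------------------------------------
# redundancy weights
# ---------------------------------------------------------------------------

@dataclass
class VariableWeights:
    """Redundancy weights w_i with their mean correlations c_i and grand mean."""

    names: list[str]
    w: np.ndarray
    c: np.ndarray
    c_bar: float

    def series(self) -> pd.Series:
        return pd.Series(self.w, index=self.names)


def redundancy_weights(X: pd.DataFrame | np.ndarray,
                       absolute: bool = True) -> VariableWeights:
    """Down-weight variables in proportion to their mean correlation with the rest.

    ``c_i`` is the mean (absolute, by default) Pearson correlation of variable i
    with every other variable, ``c_bar`` the grand mean over all ordered pairs,
    and ``w_i = 1 / (1 + c_i / c_bar)``.  If every correlation is zero the
    weights degenerate to 1 (no redundancy to mitigate).
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(arr.shape[1])]
    m = arr.shape[1]
    if m < 2:
        raise ValueError("redundancy weighting requires at least two variables")
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance variables: {bad}")
    r = np.corrcoef(arr, rowvar=False)
    if absolute:
        r = np.abs(r)
    np.fill_diagonal(r, 0.0)
    c = r.sum(axis=1) / (m - 1)
    c_bar = float(r.sum() / (m * (m - 1)))
    if c_bar == 0.0:
        w = np.ones(m)
    else:
        w = 1.0 / (1.0 + c / c_bar)
    return VariableWeights(names=names, w=w, c=c, c_bar=c_bar)


# ---------------------------------------------------------------------------
# row normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedMatrix:
    """Unit-length weighted profiles V (subjects x variables) and lengths L."""

    values: pd.DataFrame
    lengths: pd.Series


def row_normalize(S: StandardizedMatrix | pd.DataFrame,
                  w: VariableWeights | np.ndarray | None = None) -> NormalizedMatrix:
    """Scale each subject's weighted profile to unit Euclidean length.

    ``L_n = sqrt(sum_i (w_i S_in)^2)``; ``V_in = w_i S_in / L_n``.  A subject
    with L_n = 0 (identical to control means on every variable) is an error.
    """
    df = S.values if isinstance(S, StandardizedMatrix) else S
    if w is None:
        wv = np.ones(df.shape[1])
    elif isinstance(w, VariableWeights):
        wv = w.w
    else:
        wv = np.asarray(w, dtype=float)
    weighted = df.to_numpy(dtype=float) * wv
    L = np.sqrt((weighted ** 2).sum(axis=1))
    if np.any(L == 0):
        bad = [df.index[i] for i in np.flatnonzero(L == 0)]
        raise ValueError(
            f"zero weighted profile length for subjects {bad[:5]} "
            "(identical to control means on every variable)"
        )
    V = weighted / L[:, None]
    return NormalizedMatrix(
        values=pd.DataFrame(V, index=df.index, columns=df.columns),
        lengths=pd.Series(L, index=df.index, name="L"),
    )


# ---------------------------------------------------------------------------
# categorical relevance weights
# ---------------------------------------------------------------------------

@dataclass
class CategoricalWeights:
    """Per-indicator relevance: gamma, its erf squashing, and redundancy weights."""

    names: list[str]
    gamma: np.ndarray
    erf_weight: np.ndarray
    w: np.ndarray | None = None


def default_pseudo(n_controls: int) -> float:
    """Pseudo-frequency used to regularize zero case/control frequencies."""
    return 0.5 / (n_controls + 1)


def categorical_relevance(
    case_freqs: pd.Series | np.ndarray,
    control_freqs: pd.Series | np.ndarray,
    pseudo: float = 0.0,
    gamma_cap: float = 6.0,
) -> CategoricalWeights:
    """Relevance of each binary indicator from its case/control frequency ratio.

    ``gamma_j = |ln((F_j + pseudo) / (F_jC + pseudo))|`` capped at ``gamma_cap``
    (erf is already ~1 well before the cap); the usable weight is
    ``erf(gamma_j) <= 1`` so no single indicator can dominate the Tanimoto
    distance.  gamma = 0 exactly when case and control frequencies are equal,
    excluding the indicator from clustering decisions.
    """
    if isinstance(case_freqs, pd.Series):
        names = [str(i) for i in case_freqs.index]
    else:
        names = [f"x{i}" for i in range(len(case_freqs))]
    F = np.asarray(case_freqs, dtype=float)
    Fc = np.asarray(control_freqs, dtype=float)
    if F.shape != Fc.shape:
        raise ValueError("case and control frequency vectors differ in length")
    for label, arr in (("case", F), ("control", Fc)):
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{label} frequencies outside [0, 1]")
    with np.errstate(divide="ignore"):
        gamma = np.abs(np.log((F + pseudo) / (Fc + pseudo)))
    gamma = np.minimum(gamma, gamma_cap)
    # equal frequencies always map to exactly zero, regardless of pseudo
    gamma[F == Fc] = 0.0
    return CategoricalWeights(names=names, gamma=gamma, erf_weight=erf(gamma))


__all__ = [
    "impute_multiple",
    "StandardizedMatrix",
    "scale_by_controls",
    "VariableWeights",
    "redundancy_weights",
    "NormalizedMatrix",
    "row_normalize",
    "CategoricalWeights",
    "default_pseudo",
    "categorical_relevance",
]
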