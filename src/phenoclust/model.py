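"""Statsmodels-style front end: SubtypeModel (data + config) and SubtypeResults.

``SubtypeModel`` holds a case cohort, its control reference, and the scan
configuration; ``fit()`` runs the full pipeline — multiple imputation,
control-referenced scaling, redundancy weighting, row normalization,
per-imputation consensus k-means averaged over imputations, weighted
Tanimoto categorical distances, RMS fusion, semi-supervised refinement
from a partially observed extra domain, and contrast-criterion selection
over the (K, rho) grid — returning a ``SubtypeResults`` with labels,
criteria, core probabilities, and diagnostic accessors.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import criteria as crit
from .consensus import (ClusterSolution, average_consensus, consensus_matrix,
                        hierarchical_partition)
from .fuse import compute_mu, fuse, refine, subset_distance
from .io import (CATEGORICAL, CONTINUOUS, CohortTable, VariableMeta,
                 expand_categorical, read_cohort)
from .preprocess import (CategoricalWeights, categorical_relevance, default_pseudo,
                         impute_multiple, redundancy_weights, row_normalize,
                         scale_by_controls)
from .tanimoto import BinaryDesign, weighted_tanimoto_matrix

logger = logging.getLogger("phenoclust")


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters; loadable from a single YAML file."""

    seed: int = 0
    n_imputations: int = 10
    n_resamples: int = 1000
    subsample_fraction: float = 0.8
    replicates: int = 8
    k_range: list[int] = field(default_factory=lambda: list(range(2, 13)))
    rho_grid: list[float] = field(default_factory=lambda: list(np.linspace(0.05, 1.2, 24)))
    linkage: str = "average"
    fdr_level: float = 0.05
    gamma_cap: float = 6.0
    pseudo: float | None = None          # None -> 0.5 / (n_controls + 1)
    mu: float | None = None              # None -> ratio of summed weights
    weights_per_imputation: bool = False
    pac_bounds: tuple[float, float] = (0.1, 0.9)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rho_grid"] = [float(r) for r in d["rho_grid"]]
        d["pac_bounds"] = list(d["pac_bounds"])
        return d


class SubtypeModel:
    """Consensus subtyping model over a mixed-type case cohort.

    Parameters
    ----------
    cases : CohortTable
        Case table; continuous and categorical variables per its metadata.
        Columns flagged ``subset_only`` form the partially observed extra
        domain (observed rows define the refinement subset).
    controls : CohortTable, optional
        Control table; per-variable reference statistics are computed from it
        for any variable whose metadata lacks them.
    config : PipelineConfig, optional
    """

    def __init__(self, cases: CohortTable, controls: CohortTable | None = None,
                 config: PipelineConfig | None = None):
        self.cases = cases
        self.controls = controls
        self.config = config or PipelineConfig()
        self.meta = self._resolve_control_references()
        self.subset_mask = self._subset_mask()

    @classmethod
    def from_tables(cls, path_cases: str | Path, path_meta: str | Path,
                    path_controls: str | Path | None = None,
                    config: PipelineConfig | None = None) -> "SubtypeModel":
        cases = read_cohort(path_cases, path_meta)
        controls = read_cohort(path_controls, path_meta) if path_controls else None
        return cls(cases, controls, config)

    # -- reference statistics -------------------------------------------------
    def _resolve_control_references(self) -> list[VariableMeta]:
        metas = []
        for m in self.cases.meta:
            mean, sd, freq = m.control_mean, m.control_sd, m.control_freq
            if self.controls is not None and m.name in self.controls.values.columns:
                col = self.controls.values[m.name].dropna()
                if m.var_type == CONTINUOUS and (mean is None or sd is None):
                    mean = float(col.mean())
                    sd = float(col.std(ddof=1))
                elif m.var_type == CATEGORICAL and freq is None:
                    freq = float(col.mean())
            metas.append(VariableMeta(m.name, m.var_type, m.domain_group,
                                      mean, sd, freq, m.subset_only))
        return metas

    def _subset_mask(self) -> np.ndarray:
        sub_cols = [m.name for m in self.meta if m.subset_only]
        if not sub_cols:
            return np.zeros(self.cases.n_subjects, dtype=bool)
        return self.cases.values[sub_cols].notna().all(axis=1).to_numpy()

    @property
    def n_controls(self) -> int:
        return self.controls.n_subjects if self.controls is not None else 0

    # -- fitting ---------------------------------------------------------------
    def fit(self, k_range=None, rho_grid=None, seed=None,
            n_resamples=None, n_imputations=None) -> "SubtypeResults":
        cfg = self.config
        k_range = list(k_range if k_range is not None else cfg.k_range)
        has_subset = bool(self.subset_mask.any()) and any(m.subset_only for m in self.meta)
        if rho_grid is not None:
            rho_grid = list(rho_grid)
        else:
            rho_grid = list(cfg.rho_grid) if has_subset else [0.0]
        seed = cfg.seed if seed is None else seed
        n_resamples = cfg.n_resamples if n_resamples is None else n_resamples
        n_imputations = cfg.n_imputations if n_imputations is None else n_imputations
        root = np.random.SeedSequence(seed)
        ss_impute, ss_consensus, ss_subset = root.spawn(3)

        main_names = [m.name for m in self.meta if not m.subset_only]
        main = CohortTable(self.cases.values[main_names].copy(),
                           [m for m in self.meta if not m.subset_only])

        imputed = impute_multiple(
            main, n_imputations=n_imputations,
            seed=int(np.random.default_rng(ss_impute).integers(0, 2**31 - 1)),
        )
        expanded = [expand_categorical(t) for t in imputed]
        cont_names = expanded[0].continuous_names(include_subset=False)
        cat_names = expanded[0].categorical_names()
        if not cont_names:
            raise ValueError("pipeline requires at least one continuous variable")

        # weights on the first completed dataset (optionally per imputation)
        pseudo = cfg.pseudo if cfg.pseudo is not None else default_pseudo(self.n_controls)
        per_imp = []
        w_cont0 = w_cat0 = None
        for idx, t in enumerate(expanded):
            if idx == 0 or cfg.weights_per_imputation:
                S = scale_by_controls(t, names=cont_names)
                w_cont = redundancy_weights(S.values)
                if cat_names:
                    w_cat = redundancy_weights(t.values[cat_names]) if len(cat_names) > 1 \
                        else None
                else:
                    w_cat = None
                if idx == 0:
                    w_cont0, w_cat0 = w_cont, w_cat
            per_imp.append((t, w_cont if cfg.weights_per_imputation else w_cont0,
                            w_cat if cfg.weights_per_imputation else w_cat0))

        # per-imputation normalized continuous matrices and Tanimoto distances
        V_list, T_list, gamma0 = [], [], None
        for t, w_cont, w_cat in per_imp:
            S = scale_by_controls(t, names=cont_names)
            V = row_normalize(S, w_cont)
            V_list.append(V.values.to_numpy())
            if cat_names:
                X = t.values[cat_names].to_numpy(dtype=float)
                case_freqs = X.mean(axis=0)
                control_freqs = np.array([
                    t.meta_by_name(n).control_freq if t.meta_by_name(n).control_freq
                    is not None else case_freqs[i]
                    for i, n in enumerate(cat_names)
                ], dtype=float)
                gam = categorical_relevance(pd.Series(case_freqs, index=cat_names),
                                            control_freqs, pseudo=pseudo,
                                            gamma_cap=cfg.gamma_cap)
                gam.w = w_cat.w if w_cat is not None else np.ones(len(cat_names))
                if gamma0 is None:
                    gamma0 = gam
                design = BinaryDesign(X, weights=gam)
                T_list.append(weighted_tanimoto_matrix(design).D)
        T_avg = np.mean(T_list, axis=0) if T_list else None

        if cfg.mu is not None:
            mu = float(cfg.mu)
        elif T_avg is not None and cat_names:
            cat_w = (w_cat0.w if w_cat0 is not None else np.ones(len(cat_names)))
            mu = compute_mu(w_cont0.w, cat_w)
        else:
            mu = 0.0

        # subset matrix with extra variables appended, for the refinement channel
        subset_idx = np.flatnonzero(self.subset_mask)
        sub_names = [m.name for m in self.meta if m.subset_only]
        V_sub = None
        if has_subset and len(sub_names) > 0 and len(subset_idx) > 0:
            sub_table = CohortTable(
                self.cases.values.iloc[subset_idx][main_names + sub_names].copy(),
                [m for m in self.meta if not m.subset_only]
                + [m for m in self.meta if m.subset_only],
            )
            sub_imp = impute_multiple(
                sub_table, n_imputations=1,
                seed=int(np.random.default_rng(ss_subset).integers(0, 2**31 - 1)),
            )[0]
            aug_names = [n for n in cont_names] + [
                m.name for m in sub_imp.meta if m.subset_only and m.var_type == CONTINUOUS
            ]
            S_sub = scale_by_controls(sub_imp, names=aug_names)
            w_sub = redundancy_weights(S_sub.values)
            V_sub = row_normalize(S_sub, w_sub).values.to_numpy()

        # consensus per K (averaged over imputations) and BD per K
        children = {K: s for K, s in zip(k_range, ss_consensus.spawn(len(k_range)))}
        M_by_K, BD_by_K = {}, {}
        for K in k_range:
            kids = children[K].spawn(len(V_list) + 1)
            mats = [
                consensus_matrix(V, K=K, n_resamples=n_resamples,
                                 subsample_fraction=cfg.subsample_fraction,
                                 replicates=cfg.replicates, seed=kid)
                for V, kid in zip(V_list, kids[:-1])
            ]
            M_by_K[K] = average_consensus(mats)
            if V_sub is not None:
                BD_by_K[K] = subset_distance(
                    V_sub, K=K, n_resamples=n_resamples,
                    subsample_fraction=cfg.subsample_fraction,
                    replicates=cfg.replicates, seed=kids[-1])

        # criterion grid over (K, rho); labels are cheap to keep, distances are not
        rows = []
        D_by_K: dict[int, np.ndarray] = {}
        solutions: dict[tuple[int, float], ClusterSolution] = {}
        for K in k_range:
            Mk = M_by_K[K]
            D = fuse(Mk, T_avg if T_avg is not None else np.zeros_like(Mk.M), mu).D
            D_by_K[K] = D
            for rho in rho_grid:
                if V_sub is not None and rho > 0:
                    G = refine(D, BD_by_K[K], subset_idx, rho).G
                else:
                    G = D
                sol = hierarchical_partition(G, K=K, linkage=cfg.linkage)
                S_sim = 1.0 - G
                np.fill_diagonal(S_sim, 1.0)
                cc, _ = crit.contrast_criterion(S_sim, sol)
                pi = crit.core_probabilities(S_sim, sol)
                _, pcc_all = crit.pcc(pi, sol)
                rows.append({
                    "K": K, "rho": float(rho), "CC": cc, "PCC": pcc_all,
                    "PAC": crit.pac(S_sim, *cfg.pac_bounds),
                    "CS": crit.consensus_score(S_sim, sol),
                })
                solutions[(K, float(rho))] = sol
        grid = pd.DataFrame(rows)
        selection = crit.select_optimal(grid)
        K_star, rho_star = selection.selected_K, selection.selected_rho
        if V_sub is not None and rho_star > 0:
            G_star = refine(D_by_K[K_star], BD_by_K[K_star], subset_idx, rho_star).G
        else:
            G_star = D_by_K[K_star]
        sol_star = solutions[(K_star, rho_star)]
        return SubtypeResults(
            model=self, grid=selection, labels=sol_star.labels, solution=sol_star,
            solutions=solutions,
            consensus_by_K={K: cm.M for K, cm in M_by_K.items()},
            tanimoto_distance=T_avg, mu=mu, fused_distance=G_star,
            weights_continuous=w_cont0, weights_categorical=w_cat0,
            categorical_relevance=gamma0,
            subset_idx=subset_idx, seed=seed,
        )


@dataclass
class SubtypeResults:
    """Fitted subtyping solution with criteria, labels, and diagnostics."""

    model: SubtypeModel
    grid: crit.CriterionGrid
    labels: np.ndarray
    solution: ClusterSolution
    solutions: dict
    consensus_by_K: dict[int, np.ndarray]
    tanimoto_distance: np.ndarray | None
    mu: float
    fused_distance: np.ndarray
    weights_continuous: object
    weights_categorical: object
    categorical_relevance: CategoricalWeights | None
    subset_idx: np.ndarray
    seed: int

    # -- selected-solution criteria -------------------------------------------
    @property
    def K(self) -> int:
        return self.grid.selected_K

    @property
    def rho(self) -> float:
        return self.grid.selected_rho

    def similarity(self) -> np.ndarray:
        S = 1.0 - self.fused_distance
        np.fill_diagonal(S, 1.0)
        return S

    def contrast(self) -> tuple[float, np.ndarray]:
        return crit.contrast_criterion(self.similarity(), self.solution)

    def core_probabilities(self) -> pd.DataFrame:
        pi = crit.core_probabilities(self.similarity(), self.solution)
        return pd.DataFrame(pi, index=self.model.cases.subject_ids,
                            columns=[f"cluster_{k}" for k in np.unique(self.labels)])

    def pcc(self) -> tuple[np.ndarray, float]:
        pi = crit.core_probabilities(self.similarity(), self.solution)
        return crit.pcc(pi, self.solution)

    def pairwise_tests(self, alpha: float | None = None):
        alpha = alpha if alpha is not None else self.model.config.fdr_level
        return crit.pairwise_cluster_tests(self.model.cases, self.labels, alpha=alpha)

    def standard_indices(self) -> dict[str, float]:
        return crit.standard_indices(self.labels, D=self.fused_distance)

    def labels_at(self, K: int, rho: float | None = None) -> np.ndarray:
        """Cluster labels for any scanned grid point (defaults to selected rho)."""
        rho = self.rho if rho is None else float(rho)
        for (k, r), sol in self.solutions.items():
            if k == K and np.isclose(r, rho):
                return sol.labels
        raise KeyError(f"(K={K}, rho={rho}) was not scanned")

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.model.cases.subject_ids, name="cluster")

    # -- reporting -------------------------------------------------------------
    def summary(self) -> str:
        cc, per_cluster = self.contrast()
        pcc_per, pcc_all = self.pcc()
        lines = [
            "Consensus subtyping results",
            "===========================",
            f"subjects: {self.model.cases.n_subjects}   "
            f"controls: {self.model.n_controls}   "
            f"subset: {len(self.subset_idx)}",
            f"selected K = {self.K}, rho = {self.rho:.3g}, mu = {self.mu:.4g}",
            f"contrast criterion CC = {cc:.4f}   overall PCC = {pcc_all:.4f}",
            f"PCC elbow K (second-difference) = {self.grid.pcc_elbow_K}",
            *([] if self.grid.strong_structure else
              [f"note: no strong structure preference "
               f"(CC margin over other K = {self.grid.cc_margin:.4f})"]),
            "",
            "cluster   size   contrast   PCC",
        ]
        for i, k in enumerate(np.unique(self.labels)):
            lines.append(f"{k:>7}   {self.solution.sizes[i]:>4}   "
                         f"{per_cluster[i]:>8.4f}   {pcc_per[i]:.3f}")
        lines += ["", "criterion grid (per K at selected rho):"]
        at_rho = self.grid.table[np.isclose(self.grid.table["rho"], self.rho)]
        lines.append(at_rho.to_string(index=False,
                                      float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    # -- plotting --------------------------------------------------------------
    def plot_consensus(self, ax=None):
        from .plotting import plot_consensus_heatmap
        return plot_consensus_heatmap(self.similarity(), self.labels, ax=ax)

    def plot_criteria(self, ax=None):
        from .plotting import plot_criterion_curves
        return plot_criterion_curves(self.grid.table, rho=self.rho, ax=ax)

    def plot_radar(self, axes=None):
        from .plotting import plot_cluster_radar
        return plot_cluster_radar(self.model.cases, self.labels, axes=axes)


__all__ = ["PipelineConfig", "SubtypeModel", "SubtypeResults"]
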