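"""Visualization: consensus heat maps, criterion curves, per-cluster radar plots."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io import CONTINUOUS, CohortTable


def plot_consensus_heatmap(M: np.ndarray, labels=None, ax=None):
    """Consensus/similarity matrix heat map, reordered so clusters form blocks."""
    M = np.asarray(M, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    if labels is not None:
        lab = np.asarray(labels)
        order = np.lexsort((-M.mean(axis=1), lab))
        M = M[np.ix_(order, order)]
        lab = lab[order]
        bounds = np.flatnonzero(np.diff(lab)) + 0.5
        for b in bounds:
            ax.axhline(b, color="white", lw=0.6)
            ax.axvline(b, color="white", lw=0.6)
    im = ax.imshow(M, cmap="viridis", vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, label="consensus index")
    ax.set_xlabel("subjects (reordered)")
    ax.set_ylabel("subjects (reordered)")
    return ax


def plot_criterion_curves(grid: pd.DataFrame, rho: float | None = None, ax=None):
    """CC / PCC / PAC / CS versus K (at one rho if the grid was scanned over rho)."""
    if rho is not None and "rho" in grid.columns:
        grid = grid[np.isclose(grid["rho"], rho)]
    grid = grid.sort_values("K")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, style in (("CC", "-o"), ("PCC", "-s"), ("PAC", "--^"), ("CS", "--d")):
        if name in grid.columns:
            ax.plot(grid["K"], grid[name], style, label=name, ms=4)
    ax.set_xlabel("number of clusters K")
    ax.set_ylabel("criterion value")
    ax.legend()
    return ax


def plot_cluster_radar(cases: CohortTable, labels, axes=None, max_vars: int = 24):
    """Radar plots of per-cluster mean raw continuous variables by domain group."""
    lab = np.asarray(labels)
    ids = np.unique(lab)
    cont = [m for m in cases.meta if m.var_type == CONTINUOUS][:max_vars]
    names = [m.name for m in cont]
    if not names:
        raise ValueError("no continuous variables to plot")
    vals = cases.values[names].copy()
    # display on a comparable footing: control-referenced where available
    for m in cont:
        if m.control_mean is not None and m.control_sd:
            vals[m.name] = (vals[m.name] - m.control_mean) / m.control_sd
    theta = np.linspace(0, 2 * np.pi, len(names), endpoint=False)
    if axes is None:
        fig, axes = plt.subplots(1, len(ids), figsize=(3.2 * len(ids), 3.4),
                                 subplot_kw={"projection": "polar"})
        axes = np.atleast_1d(axes)
    for ax, k in zip(axes, ids):
        mean = vals[lab == k].mean().to_numpy()
        closed = np.concatenate([mean, mean[:1]])
        ax.plot(np.concatenate([theta, theta[:1]]), closed, lw=1.2)
        ax.fill(np.concatenate([theta, theta[:1]]), closed, alpha=0.25)
        ax.set_xticks(theta)
        ax.set_xticklabels(names, fontsize=5)
        ax.set_title(f"cluster {k} (n={int((lab == k).sum())})", fontsize=9)
    return axes


__all__ = ["plot_consensus_heatmap", "plot_criterion_curves", "plot_cluster_radar"]
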