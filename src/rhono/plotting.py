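"""Figure helpers: trajectory fans, bifurcation diagrams, robustness heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_trajectory_fan",
    "plot_bifurcation",
    "plot_robustness_heatmap",
]


def plot_trajectory_fan(trajectories, species_index, species_name="RhoA_GTP",
                        ax=None, seed=0):
    """Overlay one species' time courses from a multistart ensemble."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    rng = np.random.default_rng(seed)
    for traj in trajectories:
        ax.plot(traj.times, traj.states[:, species_index],
                color=rng.random(3), lw=0.8, alpha=0.8)
    ax.set_xscale("symlog", linthresh=1.0)
    ax.set_xlabel("time (model units)")
    ax.set_ylabel(f"{species_name} (nM)")
    ax.set_title("multistart ensemble")
    return ax


def plot_bifurcation(diagram, species="NO", ax=None):
    """Stable branches solid, unstable dotted; folds and interval marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    j = diagram.species_names.index(species)
    for br in diagram.branches:
        ps = np.array([bp.parameter for bp in br])
        ys = np.array([bp.state[j] for bp in br])
        st = np.array([bp.stable for bp in br])
        # split into stability-contiguous segments
        start = 0
        for i in range(1, len(br) + 1):
            if i == len(br) or st[i] != st[start]:
                style = "-" if st[start] else ":"
                ax.plot(ps[start:i], ys[start:i], style, color="k", lw=1.2)
                start = i
    for p_f, x_f in diagram.folds:
        ax.plot([p_f], [x_f[j]], "o", color="crimson", ms=5)
    if diagram.bistable_interval:
        ax.axvspan(*diagram.bistable_interval, color="0.9", zorder=0)
    ax.set_xlabel(diagram.parameter_name)
    ax.set_ylabel(f"steady-state {species} (nM)")
    return ax


def plot_robustness_heatmap(matrix, ax=None):
    """Black/white retention map with the 0% column highlighted in red."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.25 * len(matrix.parameter_names) + 1))
    cols = sorted({lv for _, lv in matrix.signed}, key=lambda v: v)
    grid = np.zeros((len(matrix.parameter_names), len(cols)))
    for i, name in enumerate(matrix.parameter_names):
        for jc, lv in enumerate(cols):
            v = matrix.signed[(name, lv)]
            grid[i, jc] = 1.0 if v else (0.5 if v is None else 0.0)
    ax.imshow(grid, cmap="gray", aspect="auto", vmin=0, vmax=1)
    if 0.0 in cols:
        j0 = cols.index(0.0)
        ax.axvline(j0, color="crimson", lw=2)
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels([f"{lv:+g}%" if lv else "0%" for lv in cols],
                       rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.parameter_names)))
    ax.set_yticklabels(matrix.parameter_names, fontsize=7)
    ax.set_title("white = bistable, black = not bistable", fontsize=8)
    return ax
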