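"""Phase-portrait and fate pie-chart figures."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .classify import FATES, FateResult
from .model import FixedPoint, ToggleParams, velocity_field

__all__ = ["plot_phase_portrait", "plot_fate_pies"]

_FATE_COLORS = {"immunogenic": "#d62728", "tolerogenic": "#1f77b4", "ambivalent": "#7f7f7f"}


def plot_phase_portrait(
    params: ToggleParams | None = None,
    fixed_points: Sequence[FixedPoint] = (),
    trajectories: Sequence[np.ndarray] = (),
    quiver_resolution: int = 20,
    out: str | Path | None = None,
):
    """Vector-field quiver with nullclines, fixed points and trajectories.

    ``trajectories`` are (n, 2) state arrays (e.g. ``Trajectory.states``).
    Returns the matplotlib figure; saves it when ``out`` is given.
    """
    p = params or ToggleParams()
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    axis = np.linspace(1e-9, p.x_max, quiver_resolution)
    grid_I, grid_T = np.meshgrid(axis, axis, indexing="xy")
    dI, dT = velocity_field((grid_I, grid_T), p)
    speed = np.hypot(dI, dT)
    ax.quiver(grid_I, grid_T, dI / speed, dT / speed, speed, cmap="Greys", alpha=0.7, scale=35)

    dense = np.linspace(1e-9, p.x_max, 400)
    DI, DT = np.meshgrid(dense, dense, indexing="xy")
    fI, fT = velocity_field((DI, DT), p)
    ax.contour(DI, DT, fI, levels=[0.0], colors="#d62728", linewidths=1.0, linestyles="--")
    ax.contour(DI, DT, fT, levels=[0.0], colors="#1f77b4", linewidths=1.0, linestyles="--")

    for states in trajectories:
        states = np.asarray(states)
        ax.plot(states[:, 0], states[:, 1], color="#2ca02c", lw=0.8, alpha=0.6)

    for fp in fixed_points:
        stable = fp.stability == "stable"
        ax.plot(
            fp.location.I,
            fp.location.T,
            marker="o" if stable else "x",
            color="black",
            markersize=9 if stable else 7,
            markerfacecolor="black" if stable else "none",
        )
        if fp.label:
            ax.annotate(
                fp.label.split("_")[0],
                fp.location,
                textcoords="offset points",
                xytext=(8, 8),
                fontsize=11,
                fontweight="bold",
            )
    ax.set_xlim(0, p.x_max)
    ax.set_ylim(0, p.x_max)
    ax.set_xlabel("immunogenic programme I")
    ax.set_ylabel("tolerogenic programme T")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig


def plot_fate_pies(result: FateResult, out: str | Path | None = None):
    """One pie per condition with fate counts and percentages."""
    conditions = list(result.counts.index)
    fig, axes = plt.subplots(1, len(conditions), figsize=(4 * len(conditions), 4), squeeze=False)
    for ax, cond in zip(axes[0], conditions):
        counts = [int(result.counts.loc[cond, f]) for f in FATES]
        total = sum(counts)
        labels = [f"{f}\n{c} ({100 * c / total:.2f}%)" for f, c in zip(FATES, counts) if c]
        ax.pie(
            [c for c in counts if c],
            labels=labels,
            colors=[_FATE_COLORS[f] for f, c in zip(FATES, counts) if c],
            textprops={"fontsize": 8},
        )
        ax.set_title(str(cond))
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig
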