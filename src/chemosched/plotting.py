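"""Optional matplotlib views of the standard analyses."""

from __future__ import annotations

import numpy as np


def _mpl():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (extra 'plot')") from exc
    return plt


def plot_trajectory(traj, ax=None, n_crit: float | None = None):
    """Volumes and carrying capacity over time; optional critical-volume line."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj.times, traj.n1, label="sensitive N1")
    ax.plot(traj.times, traj.n2, label="resistant N2")
    ax.plot(traj.times, traj.k, label="capacity K", ls="--")
    ax.plot(traj.times, traj.total, label="total", lw=2)
    if n_crit is not None:
        ax.axhline(n_crit, color="k", ls=":", label="critical volume")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("volume (mm$^3$)")
    ax.legend()
    return ax


def plot_control(solution, ax=None):
    """Optimal dose schedule as a step plot."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots()
    edges = np.linspace(0, solution.horizon, solution.control.size + 1)
    ax.stairs(solution.control, edges)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("chemotherapy dose (fraction of MTD)")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_phase_resistance(phase_df, ax=None):
    """Resistant vs sensitive cells with the N1 = N2 diagonal."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots()
    for regime, style in (("full", ":"), ("singular", "-")):
        sub = phase_df[phase_df["regime"] == regime]
        ax.plot(sub["n1"], sub["n2"], style, label=f"{regime} dose")
    lim = max(phase_df["n1"].max(), phase_df["n2"].max())
    ax.plot([0, lim], [0, lim], "--", color="gray", label="N1 = N2")
    ax.set_xlabel("sensitive N1 (mm$^3$)")
    ax.set_ylabel("resistant N2 (mm$^3$)")
    ax.legend()
    return ax


def plot_heatmap(heatmap_df, ax=None):
    """Survival-time landscape over the (u, v) plane; infinite cells masked."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots()
    pivot = heatmap_df.pivot(index="v", columns="u", values="t_s")
    data = np.ma.masked_invalid(pivot.to_numpy())
    mesh = ax.pcolormesh(pivot.columns, pivot.index, data, shading="nearest")
    plt.colorbar(mesh, ax=ax, label="survival time (days)")
    ax.set_xlabel("chemotherapy dose u")
    ax.set_ylabel("anti-angiogenic dose v")
    return ax
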