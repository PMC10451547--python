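"""Quick-look plots (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_trace", "plot_trajectory", "plot_slopes"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trace(trace, ax=None, derivative: bool = False):
    """Potential trace with the addition time marked; optionally dE/dt."""
    ax = _ax(ax)
    if derivative:
        from .induction import smoothed_derivative

        ax.plot(trace.t, smoothed_derivative(trace) * 1e3, lw=0.8)
        ax.set_ylabel("dE/dt (mV/s)")
    else:
        ax.plot(trace.t, trace.e * 1e3, lw=0.8)
        ax.set_ylabel("E (mV)")
    ax.axvline(trace.t_add, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("t (s)")
    return ax


def plot_trajectory(traj, ax=None):
    """Inhibitor and radical concentrations vs time (radical on log axis)."""
    ax = _ax(ax)
    for name, c in traj.inhibitors.items():
        ax.plot(traj.t, c * 1e3, label=name)
    ax.set_xlabel("t (s)")
    ax.set_ylabel("[InH] (mM)")
    ax2 = ax.twinx()
    ax2.semilogy(traj.t, np.maximum(traj.radical, 1e-15), color="crimson", lw=0.8)
    ax2.set_ylabel("[RO2*] (M)", color="crimson")
    if traj.inhibitors:
        ax.legend(frameon=False)
    return ax


def plot_slopes(result, ax=None):
    """Initial semilog slopes a(c0) with the extrapolated a0 intercept."""
    ax = _ax(ax)
    c0s = np.array([c for c, _ in result.slopes])
    a = np.array([s for _, s in result.slopes])
    ax.plot(c0s * 1e3, a, "o", label="measured slopes")
    ax.errorbar(
        0.0, result.a0, yerr=None if np.isnan(result.a0_se) else result.a0_se,
        marker="s", color="crimson", label=f"a0 ({result.estimator})",
    )
    ax.set_xlabel("c0 (mM)")
    ax.set_ylabel("a (1/s)")
    ax.legend(frameon=False)
    return ax
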