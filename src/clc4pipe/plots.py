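"""Diagnostic plots: I-V relations, Q-V curves with Boltzmann overlays,
current-fluorescence scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import BoltzmannFit

__all__ = ["plot_iv", "plot_qv", "plot_current_fluorescence"]


def plot_iv(iv_by_variant: dict, path=None, ax=None):
    """Steady-state current-voltage relationships, one line per variant."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for name, points in iv_by_variant.items():
        v = [p.v for p in points]
        i = [p.i_ss for p in points]
        ax.plot(v, i, marker="o", ms=3, label=name)
    ax.axhline(0, color="0.7", lw=0.8)
    ax.set_xlabel("voltage (mV)")
    ax.set_ylabel("steady-state current (nA)")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_qv(v, q, fit: BoltzmannFit | None = None, path=None, ax=None):
    """Q_off against prepulse voltage with the fitted Boltzmann overlay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(v, q, "o", ms=4, label="Q_off")
    if fit is not None and fit.converged:
        grid = np.linspace(min(v), max(v), 300)
        ax.plot(grid, fit.predict(grid), "-",
                label=f"Boltzmann: V0.5={fit.v_half:.1f} mV, k={fit.k:.1f} mV")
    ax.set_xlabel("prepulse voltage (mV)")
    ax.set_ylabel("Q_off (pC)")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_current_fluorescence(cells: pd.DataFrame, path=None, ax=None):
    """Per-cell current vs fluorescence with per-variant linear fits."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for name, sub in cells.groupby("variant"):
        f = sub["fluorescence"].to_numpy()
        i = sub["i_ss_max_v"].to_numpy()
        pts = ax.plot(f, i, "o", ms=4, label=name)
        if len(sub) >= 3 and np.ptp(f) > 0:
            coeff = np.polyfit(f, i, 1)
            grid = np.linspace(f.min(), f.max(), 10)
            ax.plot(grid, np.polyval(coeff, grid), "-",
                    color=pts[0].get_color(), lw=1)
    ax.set_xlabel("fluorescence (a.u.)")
    ax.set_ylabel("current (nA)")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
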