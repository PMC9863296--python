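"""Plot hooks: frequency-track overlays and transient-map figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_frequency_track", "plot_transient_map", "plot_spectrum"]


def plot_frequency_track(ft, reference_omega=None, ax=None):
    """Raw (markers) and smoothed (line) instantaneous frequencies; optional
    horizontal line at a reference (e.g. equilibrium) frequency."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(ft.times, ft.omega, "o", ms=3, color="goldenrod", label="raw")
    if ft.omega_smooth is not None:
        ax.plot(ft.times, ft.omega_smooth, "k--", label="smoothed")
    if reference_omega is not None:
        ax.axhline(reference_omega, color="crimson", lw=1, label="reference")
    ax.set_xlabel("time / fs")
    ax.set_ylabel(r"$\tilde\nu$ / cm$^{-1}$")
    ax.legend(frameon=False)
    return ax


def plot_spectrum(s, ax=None, **kwargs):
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(s.axis, s.intensity, **kwargs)
    ax.set_xlabel(f"axis / {s.axis_unit}")
    ax.set_ylabel("intensity / arb. u.")
    return ax


def plot_transient_map(tmap, mode: str = "heatmap", ax=None):
    """Difference map as a heat map or as stacked per-delay traces."""
    if ax is None:
        _, ax = plt.subplots()
    if mode == "heatmap":
        vmax = np.abs(tmap.intensity).max()
        im = ax.pcolormesh(
            tmap.omega_axis, tmap.delays, tmap.intensity, cmap="RdBu_r", vmin=-vmax, vmax=vmax
        )
        ax.figure.colorbar(im, ax=ax, label=r"$\delta I$ / arb. u.")
        ax.set_ylabel(r"$\Delta t$ / fs")
    elif mode == "stacked":
        span = np.abs(tmap.intensity).max()
        for i, d in enumerate(tmap.delays):
            ax.plot(tmap.omega_axis, tmap.intensity[i] + i * 1.5 * span, label=f"{d:.0f} fs")
        ax.legend(frameon=False, fontsize=8)
        ax.set_ylabel(r"$\delta I$ (offset) / arb. u.")
    else:
        raise ValueError("mode must be 'heatmap' or 'stacked'")
    ax.set_xlabel(r"$\tilde\nu$ / cm$^{-1}$")
    return ax
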