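"""Quick-look figures for simulation output.

Matplotlib figures for the standard diagnostics: cumulative mortality
curves, turtle-day density maps and circular heading histograms.  Each
function returns the Axes so callers can restyle or save.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt  # noqa: E402

from .diagnostics import DensityGrid  # noqa: E402

__all__ = ["plot_mortality", "plot_density", "plot_heading_histogram"]


def plot_mortality(curves: dict, ax=None):
    """Cumulative cold-induced mortality, one labelled curve per run."""
    if ax is None:
        _, ax = plt.subplots()
    for label, series in curves.items():
        ax.plot(series.index, series.values, label=label)
    ax.set_ylabel("fraction dead")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_density(density: DensityGrid, ax=None, log: bool = True):
    """Turtle-days-per-box map (log color scale by default)."""
    if ax is None:
        _, ax = plt.subplots()
    counts = density.counts.astype(float)
    if log:
        counts = np.log10(np.where(counts > 0, counts, np.nan))
    mesh = ax.pcolormesh(density.lon_edges, density.lat_edges, counts)
    ax.figure.colorbar(mesh, ax=ax, label="log10 turtle days" if log else "turtle days")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax


def plot_heading_histogram(edges, index, ax=None):
    """Circular histogram of swimming headings (modal bin = 100)."""
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    width = np.deg2rad(edges[1] - edges[0])
    centers = np.deg2rad(edges[:-1]) + width / 2
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)  # headings are clockwise from North
    ax.bar(centers, index, width=width, align="center")
    return ax
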