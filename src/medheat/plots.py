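"""Matplotlib views of the three analysis products.

Semantics follow the analysis conventions: trend maps colour significant
cells and grey out non-significant ones; climatology plots draw period mean
profiles with SD envelopes and event months dashed; the association
histogram shades the negative-trend part of the axis grey.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .climatology import AnomalyProfile, ClimatologyProfile
from .trends import GridSpec, TrendCellResult

__all__ = ["plot_trend_map", "plot_climatology", "plot_association_histogram"]


def plot_trend_map(results: Sequence[TrendCellResult],
                   grid: GridSpec | None = None,
                   path: str | Path | None = None,
                   ax=None):
    """Colour-coded cell map of one layer's trends; non-significant grey."""
    grid = grid or GridSpec()
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 5))
    sig = [r for r in results if r.significant]
    vmax = max((abs(r.slope) for r in sig), default=0.05)
    cmap = plt.get_cmap("RdBu_r")
    for r in results:
        lon0, lon1, lat0, lat1 = grid.bounds(r.cell)
        if r.significant:
            color = cmap(0.5 + 0.5 * np.clip(r.slope / vmax, -1, 1))
        else:
            color = (0.7, 0.7, 0.7)
        ax.add_patch(plt.Rectangle((lon0, lat0), lon1 - lon0, lat1 - lat0,
                                   facecolor=color, edgecolor="white",
                                   linewidth=0.3))
    ax.autoscale_view()
    ax.set_xlabel("longitude (°E)")
    ax.set_ylabel("latitude (°N)")
    if results:
        ax.set_title(f"temperature trend, layer {results[0].layer.label} "
                     f"(grey = not significant)")
    sm = plt.cm.ScalarMappable(cmap=cmap,
                               norm=plt.Normalize(-vmax, vmax))
    plt.colorbar(sm, ax=ax, label="°C/yr")
    if path is not None:
        ax.figure.savefig(path, dpi=110)
        plt.close(ax.figure)
    return ax


def plot_climatology(clims: Sequence[ClimatologyProfile],
                     anomalies: Sequence[AnomalyProfile] = (),
                     path: str | Path | None = None,
                     ax=None):
    """Period mean profiles (lines + SD envelopes), event months dashed."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    depths = np.arange(51)
    colors = {"P1945_1982": "black", "P1983_2011": "tab:blue"}
    for c in clims:
        col = colors.get(c.period.label, "tab:green")
        ax.plot(c.mean_t, depths, color=col, label=c.period.label)
        ax.fill_betweenx(depths, c.mean_t - c.sd_t, c.mean_t + c.sd_t,
                         color=col, alpha=0.2)
    for a in anomalies:
        # event-month mean = climatology + delta against the first reference
        if not a.delta_t:
            continue
        label, delta = next(iter(a.delta_t.items()))
        ref = next((c for c in clims if c.period.label == label), None)
        if ref is None:
            continue
        ax.plot(ref.mean_t + delta, depths, linestyle="--",
                label=f"{a.year}-{a.month:02d}")
    ax.invert_yaxis()
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("depth (m)")
    if clims:
        ax.set_title(f"{clims[0].box.name}, month {clims[0].month}")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=110)
        plt.close(ax.figure)
    return ax


def plot_association_histogram(result, path: str | Path | None = None, ax=None):
    """Occurrences over trend intervals; negative-trend region shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    edges, counts = result.bin_edges, result.histogram
    if len(edges) >= 2:
        widths = np.diff(edges)
        ax.bar(edges[:-1], counts, width=widths, align="edge",
               color="tab:red", edgecolor="black")
        if edges[0] < 0:
            ax.axvspan(edges[0], min(0.0, edges[-1]), color="0.85", zorder=0)
    ax.set_xlabel("temperature trend (°C/yr)")
    ax.set_ylabel("mortality occurrences")
    ks = result.ks
    if ks.D is not None:
        ax.set_title(f"KS vs uniform: D={ks.D:.3f}, p={ks.p:.2g}")
    if path is not None:
        ax.figure.savefig(path, dpi=110)
        plt.close(ax.figure)
    return ax
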