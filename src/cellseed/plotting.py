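"""Matplotlib views of seeding results (Agg-safe, figure-returning)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .analysis import SeedingResult  # noqa: E402

__all__ = ["plot_efficiency_curve", "plot_lateral_bins"]


def plot_efficiency_curve(*results: SeedingResult, ax=None):
    """Phi(t) for one or more runs; returns the figure."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 3.2))
    else:
        fig = ax.figure
    for res in results:
        label = res.design or "run"
        ax.plot(res.times, res.efficiency, label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("seeding efficiency $\\Phi$ (%)")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_lateral_bins(result: SeedingResult, ax=None):
    """Live/dead attached counts per lateral 1.3-mm bin; returns the figure."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 3.2))
    else:
        fig = ax.figure
    edges = result.bin_edges_mm
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = 0.4 * (edges[1] - edges[0])
    ax.bar(mids - width / 2, result.bin_counts_live, width=width,
           label="live", color="tab:green")
    ax.bar(mids + width / 2, result.bin_counts_dead, width=width,
           label="dead", color="tab:red")
    ax.set_xlabel("distance from injection side (mm)")
    ax.set_ylabel("attached cells")
    ax.set_title(result.design)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
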