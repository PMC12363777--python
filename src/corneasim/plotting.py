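"""Standard figure layouts: population dynamics with replicate spread,
ten-segment surface tracking, and pre/post-injury population comparison.

All functions take run results from :mod:`corneasim.scenario` and return a
matplotlib Figure; they never call ``show`` so they are safe headless.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import metrics
from .types import BASAL, STEM, SUPER, WING

TYPE_COLORS = {"SUPER": "#5adce6", "WING": "#3c5ae6", "BASAL": "#fab46e",
               "STEM": "#dc3c5a"}


def population_dynamics(results, stability_day=None):
    """Mean ± SD cell counts per type across replicates, plus per-type
    count histograms over the stable portion."""
    import pandas as pd

    frames = [metrics.counts_frame(r) for r in results]
    days = results[0].sample_days()[: min(len(f) for f in frames)]
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(8, 6))
    for name, color in TYPE_COLORS.items():
        stack = np.stack([f[name].to_numpy()[: len(days)] for f in frames])
        mean, sd = stack.mean(axis=0), stack.std(axis=0)
        ax0.plot(days, mean, color=color, label=name.lower())
        ax0.fill_between(days, mean - sd, mean + sd, color=color, alpha=0.25)
        stable = stack[:, days >= days[-1] / 2].ravel()
        ax1.hist(stable, bins=20, color=color, alpha=0.6, label=name.lower())
    if stability_day is not None:
        ax0.axvline(stability_day, ls="--", c="k", lw=1)
    ax0.set_xlabel("simulated days")
    ax0.set_ylabel("cell count")
    ax0.legend(ncol=4, fontsize=8)
    ax1.set_xlabel("cell count (stable window)")
    ax1.set_ylabel("frequency")
    fig.tight_layout()
    return fig


def segment_tracking(result, n_segments=10, stability_day=None):
    """Per-segment superficial surface position over time (ten X bins)."""
    days = result.sample_days()
    width = result.config.geometry.width
    series = np.array([
        metrics.segment_surface_positions(s, n_segments,
                                          result.pixel_um, width)
        for s in result.samples])
    fig, ax = plt.subplots(figsize=(8, 4))
    cmap = plt.get_cmap("tab10")
    w = width // n_segments
    for i in range(n_segments):
        ax.plot(days, series[:, i], color=cmap(i % 10), lw=0.8,
                label=f"{i * w}-{(i + 1) * w - 1} px")
    if stability_day is not None:
        ax.axvline(stability_day, ls="--", c="k", lw=1)
    ax.set_xlabel("simulated days")
    ax.set_ylabel("superficial surface position (μm)")
    ax.legend(fontsize=6, ncol=5)
    fig.tight_layout()
    return fig


def injury_comparison(results_by_label, injury_day):
    """Stacked panels of per-type counts for injury scenarios (one row per
    severity), with the injury time marked."""
    n = len(results_by_label)
    fig, axes = plt.subplots(n, 1, figsize=(8, 2.6 * n), sharex=True,
                             squeeze=False)
    for ax, (label, res) in zip(axes[:, 0], results_by_label.items()):
        df = metrics.counts_frame(res)
        days = res.sample_days()
        for name, color in TYPE_COLORS.items():
            ax.plot(days, df[name].to_numpy(), color=color, lw=1,
                    label=name.lower())
        ax.axvline(injury_day, ls="--", c="k", lw=1)
        ax.set_ylabel(label)
    axes[0, 0].legend(ncol=4, fontsize=8)
    axes[-1, 0].set_xlabel("simulated days")
    fig.tight_layout()
    return fig
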