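"""Headless-safe diagnostic plots: BIC curve and colored cluster scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .classify import ClusterLabeling
from .core import EventTable
from .io import BACKGROUND, OUTLIER
from .selection import SelectionTrace

__all__ = ["plot_bic_curve", "plot_clusters"]


def plot_bic_curve(trace: SelectionTrace, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(trace.c_values, trace.bic_values, "o-", label="subsample scan")
    if len(trace.stage2_c_values):
        ax.plot(
            trace.stage2_c_values,
            trace.stage2_bic_values,
            "s--",
            label="full-data refit",
        )
    ax.axvline(trace.chosen_c, color="gray", ls=":", label=f"chosen c = {trace.chosen_c}")
    ax.set_xlabel("number of components c")
    ax.set_ylabel("BIC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_clusters(events: EventTable, labeling: ClusterLabeling, path) -> None:
    """Scatter with colored foreground clusters and gray background/outliers."""
    a = labeling.event_assignment
    fig, ax = plt.subplots(figsize=(6, 6))
    gray = (a == BACKGROUND) | (a == OUTLIER)
    ax.scatter(*events.values[gray].T, s=1, c="lightgray", rasterized=True)
    cmap = plt.get_cmap("tab20")
    for j in np.unique(a[a >= 0]):
        sel = a == j
        ax.scatter(*events.values[sel].T, s=1, color=cmap(j % 20), rasterized=True)
    ax.set_xlabel(events.channel_names[0])
    ax.set_ylabel(events.channel_names[1])
    ax.set_xlim(0, 65536)
    ax.set_ylim(0, 65536)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
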