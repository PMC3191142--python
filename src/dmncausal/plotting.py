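"""Figures: band-styled group causal graphs and the hub-index scattergram."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .timeseries import DEFAULT_HUB_LABELS

#: Edge style per proportion band (width, color, linestyle); edges shown by
#: fewer than half the subjects are not drawn.
_BAND_STYLE = {
    "above_80": (3.0, "black", "-"),
    "60_to_80": (2.0, "darkorange", "-"),
    "50_to_60": (1.2, "green", "--"),
}


def plot_group_graph(
    proportions: pd.DataFrame,
    node_labels: Sequence[str],
    hub_labels: Sequence[str] = DEFAULT_HUB_LABELS,
    ax: "plt.Axes | None" = None,
    title: str | None = None,
) -> "plt.Axes":
    """Ring-layout directed graph with band-styled edges.

    ``proportions`` is the output of
    :func:`dmncausal.network.group_edge_proportions`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    n = len(node_labels)
    angles = 2 * np.pi * np.arange(n) / n + np.pi / 2
    pos = {lab: (np.cos(a), np.sin(a)) for lab, a in zip(node_labels, angles)}
    for _, row in proportions.iterrows():
        style = _BAND_STYLE.get(row["band"])
        if style is None:
            continue
        lw, color, ls = style
        x0, y0 = pos[row["source"]]
        x1, y1 = pos[row["target"]]
        ax.annotate(
            "",
            xy=(x1, y1),
            xytext=(x0, y0),
            arrowprops=dict(
                arrowstyle="-|>", lw=lw, color=color, linestyle=ls,
                shrinkA=18, shrinkB=18,
            ),
        )
    hubs = set(hub_labels)
    for lab, (x, y) in pos.items():
        ax.scatter([x], [y], s=900, c="red" if lab in hubs else "royalblue", zorder=3)
        ax.annotate(lab, (x, y), ha="center", va="center", color="white",
                    fontsize=8, zorder=4)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    return ax


def plot_hub_index_scatter(
    hub_table: pd.DataFrame,
    cutoff: float | None = None,
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Per-subject D_outer/D_all by group, with the ROC cutoff line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 5))
    groups = list(dict.fromkeys(hub_table["group"]))
    rng = np.random.default_rng(0)  # fixed horizontal jitter for display only
    for i, g in enumerate(groups):
        vals = hub_table.loc[hub_table.group == g, "ratio"].dropna()
        x = i + rng.uniform(-0.12, 0.12, size=len(vals))
        ax.scatter(x, vals, alpha=0.8, label=g)
    if cutoff is not None:
        ax.axhline(cutoff, color="k", lw=1.5)
        ax.annotate(f" cutoff = {cutoff:.3f}", (len(groups) - 0.5, cutoff),
                    va="bottom", fontsize=8)
    ax.set_xticks(range(len(groups)), groups)
    ax.set_ylabel(r"$D_{outer}/D_{all}$")
    ax.set_ylim(0, 1.05)
    return ax
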