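"""Matplotlib helpers for the two diagram types used throughout the package."""

from __future__ import annotations

import numpy as np

from .clustering import ClusterResult, tomato_diagram
from .homology import PersistenceDiagram, diagram_histogram


def plot_tomato_diagram(cr: ClusterResult, tau: float | None = None, ax=None):
    """Birth/death scatter of candidate clusters; the persistence threshold is
    drawn as a line parallel to the diagonal.  −inf deaths are pinned below
    the axis range."""
    import matplotlib.pyplot as plt

    births, deaths, _ = tomato_diagram(cr)
    ax = ax or plt.gca()
    finite = np.isfinite(deaths)
    floor = (deaths[finite].min() if finite.any() else 0.0) - 0.1 * (births.max() or 1.0) - 1.0
    shown = np.where(finite, deaths, floor)
    ax.scatter(births, shown, s=12, c=np.where(finite, "C0", "C3"))
    lim = births.max() * 1.05 + 1
    ax.plot([floor, lim], [floor, lim], "k-", lw=0.8)
    if tau is not None:
        ax.plot([floor, lim], [floor - tau, lim - tau], "k--", lw=0.8)
    ax.set_xlabel("birth density (detections)")
    ax.set_ylabel("death density (detections)")
    return ax


def plot_persistence_diagram(
    pd_: PersistenceDiagram, pers_threshold: float | None = None, ax=None,
    heatmap_bin: float | None = None,
):
    """Persistence diagram scatter (or a 1-unit-binned heat map when dense)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    colors = {0: "C7", 1: "C0", 2: "C1"}
    if heatmap_bin is not None:
        counts, be, de = diagram_histogram(pd_, dim=1, bin_size=heatmap_bin)
        ax.pcolormesh(be, de, counts.T, cmap="viridis")
    else:
        for dim in np.unique(pd_.features["dim"]):
            f = pd_.by_dim(int(dim))
            finite = np.isfinite(f["death"])
            cap = pd_.max_scale * 1.05
            ax.scatter(f["birth"], np.where(finite, f["death"], cap),
                       s=12, c=colors.get(int(dim), "C4"), label=f"H{int(dim)}")
        ax.legend(loc="lower right")
    lim = pd_.max_scale * 1.05
    ax.plot([0, lim], [0, lim], "k-", lw=0.8)
    if pers_threshold is not None:
        ax.plot([0, lim], [pers_threshold, lim + pers_threshold], "k--", lw=0.8)
    ax.set_xlabel("birth scale (nm)")
    ax.set_ylabel("death scale (nm)")
    return ax
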