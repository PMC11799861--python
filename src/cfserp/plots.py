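"""Optional figure helpers (require matplotlib, not a core dependency).

Quick visual checks of a run: fearful-minus-neutral difference waves per
contrast level, and a flat-projected topography of a cluster or template.
"""

from __future__ import annotations

import numpy as np

from .cluster import ClusterResult
from .preproc import ConditionMeans
from .synth import MAIN_LEVELS, SensorGraph


def _mpl():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as err:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip extra 'plot')") from err
    return plt


def difference_waves(
    cm: ConditionMeans,
    cfs: bool,
    channels: np.ndarray | None = None,
    ax=None,
):
    """Grand-average fearful-minus-neutral waveforms, one line per contrast.

    ``channels`` restricts the spatial average (boolean mask or indices);
    default: all channels of ``cm``.
    """
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    if channels is None:
        channels = np.arange(cm.data.shape[2])
    channels = np.asarray(channels)
    if channels.dtype == bool:
        channels = np.flatnonzero(channels)
    for lev in MAIN_LEVELS:
        f = cm.data[:, cm.cell_index("fearful", lev, cfs)][:, channels].mean((0, 1))
        n = cm.data[:, cm.cell_index("neutral", lev, cfs)][:, channels].mean((0, 1))
        ax.plot(cm.times, f - n, label=lev)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("fearful - neutral (μV)")
    ax.set_title("CFS" if cfs else "noCFS")
    ax.legend(title="contrast", fontsize=8)
    return ax


def topography(
    values: np.ndarray,
    layout: SensorGraph,
    highlight: ClusterResult | None = None,
    ax=None,
):
    """Scalp map approximation: channels flat-projected from above, colored
    by ``values`` (one scalar per channel); cluster channels outlined."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x, y = layout.positions[:, 0], layout.positions[:, 1]
    sc = ax.scatter(x, y, c=values, s=120, cmap="RdBu_r", edgecolors="gray")
    if highlight is not None:
        members = np.unique(highlight.channels)
        ax.scatter(
            x[members], y[members], facecolors="none", edgecolors="k",
            s=220, linewidths=1.5,
        )
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    plt.colorbar(sc, ax=ax, shrink=0.8, label="μV or F")
    return ax
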