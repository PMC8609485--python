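"""Inspection plots (optional; requires the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .erp import ERPSet
from .montage import Montage


def topography_difference(
    erps: ERPSet,
    montage: Montage,
    cond_a: str,
    cond_b: str,
    window_ms: tuple[float, float],
    ax=None,
):
    """Scatter topoplot of the window-mean difference ``cond_a - cond_b``.

    For eyeballing component distributions when choosing pools; not part of
    the statistical pipeline.
    """
    import matplotlib.pyplot as plt

    t = erps.times_ms
    sel = (t >= window_ms[0]) & (t < window_ms[1])
    diff = (erps.averages[cond_a] - erps.averages[cond_b])[:, sel].mean(axis=1)
    u = montage.unit_positions()
    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(u[:, 0], u[:, 1], c=diff, cmap="RdBu_r",
                    vmin=-np.abs(diff).max(), vmax=np.abs(diff).max())
    ax.set_aspect("equal")
    ax.set_title(f"{cond_a} − {cond_b}, {window_ms[0]:.0f}–{window_ms[1]:.0f} ms")
    plt.colorbar(sc, ax=ax, label="µV")
    return ax
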