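"""Quick-look figures: annotated traces and PCA trajectory planes."""

from __future__ import annotations

import numpy as np

from .events import EventTable, Trace

_CLASS_COLORS = {"spike": "tab:blue", "burst": "tab:red", "other": "tab:gray"}


def plot_trace(trace: Trace, table: EventTable | None = None, ax=None,
               t_range_s: tuple[float, float] | None = None):
    """Voltage trace with detected events shaded by class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    t = trace.t_s
    v = trace.v_mv
    if t_range_s is not None:
        sel = (t >= t_range_s[0]) & (t <= t_range_s[1])
        t, v = t[sel], v[sel]
    ax.plot(t, v, lw=0.5, color="k")
    if table is not None:
        ax.axhline(table.baseline_mv, color="tab:green", lw=0.8, ls="--",
                   label="baseline")
        for ev in table.events:
            if t_range_s and not (t_range_s[0] <= ev.start_s <= t_range_s[1]):
                continue
            ax.axvspan(ev.start_s, ev.end_s, alpha=0.2,
                       color=_CLASS_COLORS.get(ev.klass, "tab:gray"))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("V (mV)")
    return ax


def plot_trajectories(basal_scores, stim_scores, labels=None, ax=None,
                      components=("PC1", "PC2")):
    """Basal (open) to stimulated (filled) positions in the PC plane,
    connected per cell."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cx, cy = components
    stim = stim_scores.loc[basal_scores.index]
    colors = None
    if labels is not None:
        groups = labels.loc[basal_scores.index].astype(str)
        palette = {g: f"C{i}" for i, g in enumerate(sorted(groups.unique()))}
        colors = groups.map(palette)
    for i, cell in enumerate(basal_scores.index):
        c = colors.iloc[i] if colors is not None else "k"
        x0, y0 = basal_scores.loc[cell, cx], basal_scores.loc[cell, cy]
        x1, y1 = stim.loc[cell, cx], stim.loc[cell, cy]
        ax.plot([x0, x1], [y0, y1], color=c, lw=0.8, alpha=0.6)
        ax.scatter([x0], [y0], facecolors="none", edgecolors=c, s=25)
        ax.scatter([x1], [y1], color=c, s=25)
    ax.set_xlabel(cx)
    ax.set_ylabel(cy)
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    return ax
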