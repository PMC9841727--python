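"""PV-loop figure rendering (loops plus ESPVR/EDPVR lines)."""

from __future__ import annotations

import numpy as np

from .pvloop import PVLoopSet, PVRFit

__all__ = ["plot_loops", "plot_bland_altman"]


def plot_loops(loops: PVLoopSet, espvr: PVRFit | None = None, edpvr: PVRFit | None = None, ax=None):
    """Plot the per-beat PV loops in black with the ESPVR (blue) and EDPVR
    (red) fit lines through the end-systolic / end-diastolic points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for b in loops.beats:
        ax.plot(b.volume, b.pressure, color="black", lw=0.8)
    es, ed = loops.es_points, loops.ed_points
    ax.plot(es[:, 0], es[:, 1], "o", color="tab:blue", ms=4, label="end-systole")
    ax.plot(ed[:, 0], ed[:, 1], "o", color="tab:red", ms=4, label="end-diastole")
    v_span = np.array([min(ed[:, 0].min(), es[:, 0].min()) - 5, ed[:, 0].max() + 5])
    if espvr is not None:
        ax.plot(v_span, espvr.slope * v_span + espvr.intercept, color="tab:blue", lw=1.5,
                label=f"ESPVR {espvr.slope:.2f} mmHg/ml")
    if edpvr is not None:
        ax.plot(v_span, edpvr.slope * v_span + edpvr.intercept, color="tab:red", lw=1.5,
                label=f"EDPVR {edpvr.slope:.2f} mmHg/ml")
    ax.set_xlabel("LV volume (ml)")
    ax.set_ylabel("LV pressure (mmHg)")
    ax.legend(fontsize=8)
    return ax


def plot_bland_altman(x, y, ax=None, labels=("method A", "method B")):
    """Bland-Altman plot: differences vs means, bias and limits of agreement."""
    import matplotlib.pyplot as plt

    from .agreement import bland_altman

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    bias, lo, hi = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(0.5 * (x + y), x - y, s=14, color="black")
    ax.axhline(bias, color="black", lw=1.2)
    for lim in (lo, hi):
        ax.axhline(lim, color="black", lw=1.0, ls="--")
    ax.set_xlabel(f"mean of {labels[0]} and {labels[1]}")
    ax.set_ylabel(f"{labels[0]} - {labels[1]}")
    return ax
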