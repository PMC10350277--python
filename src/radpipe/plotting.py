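"""Kaplan-Meier plotting helpers."""

from __future__ import annotations

import numpy as np

from .survival_eval import SurvivalData, kaplan_meier

__all__ = ["plot_km_groups"]


def plot_km_groups(groups, survival: SurvivalData, ax=None,
                   max_time: float | None = None):
    """Plot Kaplan-Meier curves with Greenwood 95% bands per risk group.

    Returns the matplotlib Axes.  Import of matplotlib is deferred so the
    numeric pipeline never requires a display backend.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    groups = np.asarray(groups)
    for label in np.unique(groups):
        sel = groups == label
        km = kaplan_meier(survival.subset(sel))
        t = np.concatenate([[0.0], km.times])
        s = np.concatenate([[1.0], km.survival])
        lo = np.concatenate([[1.0], km.ci_lower])
        hi = np.concatenate([[1.0], km.ci_upper])
        ax.step(t, s, where="post", label=f"{label} (n={sel.sum()})")
        ax.fill_between(t, lo, hi, step="post", alpha=0.2)
    if max_time is not None:
        ax.set_xlim(0, max_time)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("overall survival probability")
    ax.legend()
    return ax
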