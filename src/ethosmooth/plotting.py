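"""Plots mirroring the standard behavioural-summary figures:
stacked hourly activity profiles, bout-length and inter-event histograms,
evidence curves and classified activity scatter plots."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import BehaviourClass

_COLORS = {
    BehaviourClass.FEEDING: "tab:red",
    BehaviourClass.MOBILE: "tab:blue",
    BehaviourClass.STATIONARY: "tab:green",
}


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_hourly_profile(profile, ax=None):
    """Stacked per-hour class fractions (feeding bottom, stationary top)."""
    ax = _axes(ax)
    hours = np.arange(24)
    frac = np.nan_to_num(profile.fractions)
    bottom = np.zeros(24)
    for j, c in enumerate(BehaviourClass):
        ax.bar(hours, frac[:, j], bottom=bottom, color=_COLORS[c], label=c.label)
        bottom += frac[:, j]
    ax.set_xlabel("hour of day (local)")
    ax.set_ylabel("fraction of bins")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize="small")
    return ax


def plot_duration_histogram(hist, unit: str = "min", ax=None):
    """Histogram of bout lengths or inter-event intervals."""
    ax = _axes(ax)
    width = hist.bin_width / pd.Timedelta(minutes=1)
    if unit == "days":
        width /= 60 * 24
    centers = (hist.edges[:-1] + hist.edges[1:]) / 2 * width
    ax.bar(centers, hist.counts, width=width * 0.9)
    ax.set_xlabel(f"duration ({unit})")
    ax.set_ylabel("number of events")
    return ax


def plot_evidence_curve(curve, ax=None):
    """Summed held-out log evidence against the feeding stay probability."""
    ax = _axes(ax)
    ax.plot(curve.grid, curve.log_evidence, marker="o")
    ax.axvline(curve.argmax, color="tab:red", lw=1)
    ax.set_xlabel("feeding stay probability")
    ax.set_ylabel("log evidence (summed over held-out sessions)")
    return ax


def plot_classified_activity(activity, states, ax=None, max_points=20_000):
    """Activity counts coloured by assigned class (cluster-structure view)."""
    ax = _axes(ax)
    n = len(activity)
    idx = np.arange(n) if n <= max_points else np.linspace(0, n - 1, max_points, dtype=int)
    for c in BehaviourClass:
        sel = idx[states.states[idx] == int(c)]
        ax.scatter(
            activity.counts[sel, 0], activity.counts[sel, 1],
            s=4, color=_COLORS[c], label=c.label, alpha=0.5,
        )
    ax.set_xlabel("activity count (x)")
    ax.set_ylabel("activity count (y)")
    ax.legend(loc="upper left", fontsize="small")
    return ax
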