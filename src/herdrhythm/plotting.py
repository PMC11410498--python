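"""Plotting helpers: harmonic-period proportion bars and average-MI actogram
lines per treatment group.  Qualitative aids only — nothing downstream
asserts on figure content."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_harmonic_proportions", "plot_average_mi"]


def plot_harmonic_proportions(proportions: pd.DataFrame, ax=None):
    """Bar chart of the share of significant harmonic periods per group.

    ``proportions`` is the tidy frame from the harmonic catalog
    (columns group, period_h, proportion).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    wide = proportions.pivot(index="period_h", columns="group", values="proportion")
    wide = wide.sort_index(ascending=False).fillna(0.0)
    wide.plot.bar(ax=ax)
    ax.set_xlabel("harmonic period length (h)")
    ax.set_ylabel("proportion of significant periods")
    ax.legend(title="contact time")
    return ax


def plot_average_mi(series_list, ax=None, label: str | None = None):
    """Average motion index over cows by 15-min time of day (one line)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    frames = []
    for s in series_list:
        df = s.data[["motion_index"]].copy()
        df["tod"] = df.index.hour * 60 + df.index.minute
        frames.append(df)
    allf = pd.concat(frames)
    prof = allf.groupby("tod")["motion_index"].mean()
    ax.plot(prof.index / 60.0, prof.values, label=label)
    ax.set_xlabel("time of day (h, UTC)")
    ax.set_ylabel("mean motion index / 15 min")
    if label:
        ax.legend()
    return ax
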