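"""Diagnostic plots: window-variance Manhattan and genetic trend."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["manhattan_plot", "trend_plot"]


def manhattan_plot(window_table: pd.DataFrame, ax=None, title: str | None = None):
    """Plot per-window % genomic variance along the genome.

    ``window_table`` is the output of
    :func:`ssgblup.weights.window_variance_explained`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for chrom, grp in window_table.groupby("chrom", sort=True):
        x = grp["mid_pos"].to_numpy(dtype=float) + offset
        ax.scatter(x, grp["pct_var"], s=12,
                   color="C0" if int(chrom) % 2 else "C1")
        ticks.append(x.mean())
        labels.append(str(chrom))
        offset = x.max() + np.ptp(grp["mid_pos"].to_numpy(dtype=float)) * 0.02 + 1
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("% variance explained")
    if title:
        ax.set_title(title)
    return ax.figure


def trend_plot(trend_table: pd.DataFrame, slope: float | None = None, ax=None):
    """Plot the standardized genetic trend (mean EBV/σa per birth year)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(trend_table["birth_year"], trend_table["mean_std_ebv"], "o-")
    if slope is not None and len(trend_table) > 1:
        x = trend_table["birth_year"].to_numpy(dtype=float)
        y = trend_table["mean_std_ebv"].to_numpy(dtype=float)
        b0 = y.mean() - slope * x.mean()
        ax.plot(x, b0 + slope * x, "--", color="grey",
                label=f"{slope:+.3f} SD/year")
        ax.legend()
    ax.set_xlabel("birth year")
    ax.set_ylabel("mean EBV (genetic SD)")
    return ax.figure
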