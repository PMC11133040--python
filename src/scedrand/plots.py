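"""Diagnostic plots: the raw time series and the randomization distribution.

Matplotlib is used with whatever backend is active; the CLI forces ``Agg``.
Plots are side effects only — every number they show is also written to a
delimited table so downstream checks never read pixels.
"""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np

from .io import SCEDSeries
from .rtest import ScanResult, TestResult

__all__ = ["time_series_plot", "statistic_plot", "scan_plot"]


def time_series_plot(
    series: SCEDSeries,
    ax=None,
    *,
    ymin: float | None = None,
    ymax: float | None = None,
    title: str = "",
):
    """Raw scores against session number with a phase-change line.

    A fixed y-range (``ymin``/``ymax``) keeps graphs comparable across cases,
    which matters for visual analysis.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(series.occasions, series.scores, marker="o", color="black", lw=1)
    if series.is_contiguous_ab:
        ax.axvline(series.n_A + 0.5, color="gray", ls="--", lw=1)
    if ymin is not None and ymax is not None:
        ax.set_ylim(ymin, ymax)
    ax.set_xlabel("Session")
    ax.set_ylabel("Score")
    if title:
        ax.set_title(title)
    return ax


def statistic_plot(result: TestResult, ax=None, *, title: str = ""):
    """Statistic per admissible division; the observed one in green/red.

    Green marks a favorable observed result (statistic above the zero line,
    i.e. in the direction of the desired change), red an unfavorable one.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    x = np.arange(1, result.m + 1)
    ax.axhline(0.0, color="gray", lw=1)
    ax.plot(x, result.pseudovalues, marker="o", color="black", lw=1, zorder=2)
    obs_color = "green" if result.favorable else "red"
    ax.plot(
        x[result.observed_index],
        result.pseudovalues[result.observed_index],
        marker="o",
        markersize=10,
        color=obs_color,
        zorder=3,
    )
    ax.set_ylim(-1.05, 1.05)
    ax.set_xticks(x)
    ax.set_xlabel("Admissible data division")
    ax.set_ylabel("Pearson r")
    if title:
        ax.set_title(title)
    return ax


def scan_plot(scan: ScanResult, fig=None):
    """One statistic panel per scan scenario (duration or latency)."""
    k = len(scan.results)
    ncols = min(3, k)
    nrows = int(np.ceil(k / ncols))
    if fig is None:
        fig, axes = plt.subplots(
            nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False
        )
    else:
        axes = fig.subplots(nrows, ncols, squeeze=False)
    labels = scan.scenario_labels()
    for i, (res, lab) in enumerate(zip(scan.results, labels)):
        statistic_plot(res, ax=axes[i // ncols][i % ncols], title=lab)
    for j in range(k, nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.tight_layout()
    return fig
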