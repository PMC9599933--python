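"""Bland-Altman scatter and MAE bar figures for agreement reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .agreement import PairedEstimates, bland_altman

__all__ = ["bland_altman_plot", "mae_bars"]


def bland_altman_plot(pairs: PairedEstimates, ax=None, loa_multiplier: float = 1.96):
    """Scatter of (mean, difference) with MOD (dashed) and LOA (solid) lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mean = 0.5 * (pairs.est + pairs.ref)
    diff = pairs.est - pairs.ref
    ax.scatter(mean, diff, s=8, alpha=0.4)
    ba = bland_altman(pairs, loa_multiplier)
    ax.axhline(ba.mod, ls="--", color="k", lw=1)
    ax.axhline(ba.loa_low, color="k", lw=1)
    ax.axhline(ba.loa_high, color="k", lw=1)
    unit = "bpm" if pairs.vital == "hr" else "BrPM"
    ax.set_xlabel(f"mean of methods ({unit})")
    ax.set_ylabel(f"difference est - ref ({unit})")
    ax.set_title(f"{pairs.vital.upper()} {pairs.sensor} {pairs.posture} "
                 f"L={pairs.window_length:g}s")
    return ax


def mae_bars(report, vital: str, ax=None):
    """Grouped MAE bars per window length, one bar pair per sensor."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    df = report.summary
    df = df[(df["metric"] == "mae") & (df["vital"] == vital)]
    pooled = df.groupby(["sensor", "window_s"])["value"].mean().reset_index()
    sensors = sorted(pooled["sensor"].unique())
    windows = sorted(pooled["window_s"].unique())
    width = 0.8 / max(len(sensors), 1)
    x = np.arange(len(windows))
    for j, sensor in enumerate(sensors):
        vals = [pooled[(pooled.sensor == sensor) & (pooled.window_s == w)]["value"].mean()
                for w in windows]
        ax.bar(x + j * width, vals, width, label=sensor)
    ax.set_xticks(x + width * (len(sensors) - 1) / 2)
    ax.set_xticklabels([f"{w:g}" for w in windows])
    ax.set_xlabel("window length (s)")
    ax.set_ylabel("MAE (bpm)" if vital == "hr" else "MAE (BrPM)")
    ax.set_title(f"{vital.upper()} mean absolute error")
    ax.legend()
    return ax
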