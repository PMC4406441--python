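"""Plotting helpers: peristimulus panels and duration-response curves."""

from __future__ import annotations

from typing import Optional

import matplotlib.pyplot as plt
import pandas as pd

from .stimulus import PeristimulusSet


def plot_peristimulus(
    pset: PeristimulusSet,
    ax: Optional[plt.Axes] = None,
    color: str = "C0",
    label: Optional[str] = None,
) -> plt.Axes:
    """Mean peristimulus trace with an SD band and a stimulus marker."""
    if ax is None:
        _, ax = plt.subplots()
    m, s = pset.mean, pset.sd
    ax.plot(pset.time_ms, m, color=color, label=label)
    ax.fill_between(pset.time_ms, m - s, m + s, color=color, alpha=0.3, linewidth=0)
    ax.axvline(0.0, color="tab:blue", linestyle="--", linewidth=1)
    ax.set_xlabel("time from stimulation (ms)")
    ax.set_ylabel("ΔF/F")
    if label:
        ax.legend()
    return ax


def plot_duration_curve(
    curve: pd.DataFrame, ax: Optional[plt.Axes] = None, **errorbar_kw
) -> plt.Axes:
    """Response amplitude vs stimulus duration (log-duration axis)."""
    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        curve["duration_ms"], curve["mean_amplitude"], yerr=curve["sd_amplitude"],
        marker="o", **errorbar_kw,
    )
    ax.set_xscale("log", base=2)
    ax.set_xlabel("stimulus duration (ms)")
    ax.set_ylabel("response amplitude (ΔF/F)")
    return ax
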