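"""Frequency-profile plot: per-window gain/loss frequency along the genome.

Gains plot upward in red and losses downward in green, one panel of the
genome axis per figure, the convention aCGH cohort summaries use.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from agecna.copynumber_calls import CallState, CallTrack, WindowGrid

__all__ = ["plot_frequency_profile"]


def plot_frequency_profile(
    calls_by_sample: Sequence[CallTrack],
    grid: WindowGrid,
    path: str | Path,
    title: str = "",
) -> None:
    states = np.stack([c.states for c in calls_by_sample])
    n = states.shape[0]
    gain_freq = np.mean(states == int(CallState.GAIN), axis=0)
    loss_freq = np.mean(states == int(CallState.LOSS), axis=0)
    masked = np.all(states == int(CallState.MASKED), axis=0)
    gain_freq[masked] = np.nan
    loss_freq[masked] = np.nan

    x = np.arange(len(grid))
    fig, ax = plt.subplots(figsize=(12, 3))
    ax.fill_between(x, 0, gain_freq, step="mid", color="red", alpha=0.8,
                    label=f"gain (n={n})")
    ax.fill_between(x, 0, -loss_freq, step="mid", color="green", alpha=0.8,
                    label="loss")
    bounds = np.flatnonzero(grid.chromosomes[1:] != grid.chromosomes[:-1]) + 1
    for b in bounds:
        ax.axvline(b - 0.5, color="grey", lw=0.5)
    ax.axhline(0, color="black", lw=0.5)
    ax.set_ylim(-1, 1)
    ax.set_xlim(0, len(grid))
    ax.set_xlabel("window along genome")
    ax.set_ylabel("aberration frequency")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
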