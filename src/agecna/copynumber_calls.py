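"""Window-averaged copy-number calling.

Probe-level log2 ratios are averaged over fixed runs of 10 consecutive
probes (~60 kb at 6 kb spacing); a window is called GAIN when its mean
strictly exceeds the gain cut (+0.1 by default), LOSS when strictly below
the loss cut (-0.1), and NORMAL otherwise.  Windows intersecting any
exclusion mask (telomere, centromere, acrocentric p-arm, sex chromosome)
are MASKED regardless of their mean.  Thresholds can instead be calibrated
from a self-control hybridization so the empirical false-positive rate on
autosomal windows hits a target (defaults 0.005 for gains, 0.007 for
losses).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np

from agecna.genome_model import GenomeBuild, MaskSet
from agecna.synthetic_cohort import ProbeMap, RatioTrack

__all__ = [
    "CallState",
    "Thresholds",
    "WindowGrid",
    "CallTrack",
    "build_windows",
    "window_means",
    "empirical_fpr",
    "calibrate_thresholds",
    "call_states",
    "window_mask_flags",
]

logger = logging.getLogger(__name__)


class CallState(IntEnum):
    LOSS = -1
    NORMAL = 0
    GAIN = 1
    MASKED = 2


@dataclass(frozen=True)
class Thresholds:
    """Log2-ratio cuts applied to window means (strict inequalities)."""

    gain_cut: float = 0.1
    loss_cut: float = -0.1

    def __post_init__(self) -> None:
        if not (self.loss_cut < 0 < self.gain_cut):
            raise ValueError(
                f"need loss_cut < 0 < gain_cut, got {self.loss_cut}, {self.gain_cut}"
            )


@dataclass(frozen=True)
class WindowGrid:
    """Fixed-probe-count windows partitioning each chromosome's probes.

    ``probe_starts``/``probe_stops`` are half-open index ranges into the
    probe map; the last window on a chromosome may hold fewer probes.
    """

    chromosomes: np.ndarray  # per window
    starts: np.ndarray  # genomic bp, first probe start
    ends: np.ndarray  # genomic bp, last probe end
    probe_starts: np.ndarray
    probe_stops: np.ndarray
    probes_per_window: int

    def __len__(self) -> int:
        return len(self.starts)

    def n_probes(self, w: int) -> int:
        return int(self.probe_stops[w] - self.probe_starts[w])

    def bp_lengths(self) -> np.ndarray:
        return self.ends - self.starts


@dataclass
class CallTrack:
    """Per-window states and means for one sample."""

    sample_id: str
    states: np.ndarray  # CallState values
    window_means: np.ndarray

    def __post_init__(self) -> None:
        if len(self.states) != len(self.window_means):
            raise ValueError("states and window_means length mismatch")


def build_windows(probe_map: ProbeMap, probes_per_window: int = 10) -> WindowGrid:
    """Partition each chromosome's probes into consecutive fixed-size windows.

    Windows never span a chromosome boundary; genomic bounds are
    [first probe start, last probe end).
    """
    if len(probe_map) == 0:
        raise ValueError("empty probe map")
    if probes_per_window < 1:
        raise ValueError("probes_per_window must be >= 1")
    chroms, w_start, w_end, p_start, p_stop = [], [], [], [], []
    # probes are stored grouped by chromosome in map order
    unique_chroms = list(dict.fromkeys(probe_map.chromosomes.tolist()))
    for chrom in unique_chroms:
        idx = probe_map.chromosome_index(chrom)
        lo, hi = idx[0], idx[-1] + 1
        for a in range(lo, hi, probes_per_window):
            b = min(a + probes_per_window, hi)
            chroms.append(chrom)
            w_start.append(int(probe_map.starts[a]))
            w_end.append(int(probe_map.ends[b - 1]))
            p_start.append(a)
            p_stop.append(b)
    return WindowGrid(
        chromosomes=np.asarray(chroms, dtype=object),
        starts=np.asarray(w_start, dtype=int),
        ends=np.asarray(w_end, dtype=int),
        probe_starts=np.asarray(p_start, dtype=int),
        probe_stops=np.asarray(p_stop, dtype=int),
        probes_per_window=probes_per_window,
    )


def window_means(track: RatioTrack, grid: WindowGrid) -> np.ndarray:
    """Arithmetic mean of non-missing probe ratios per window.

    A window whose probes are all missing gets NaN (undefined).
    """
    values = track.values
    if len(values) != int(grid.probe_stops[-1]):
        raise ValueError(
            f"{track.sample_id}: track has {len(values)} probes but grid expects "
            f"{int(grid.probe_stops[-1])}"
        )
    means = np.empty(len(grid))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for w in range(len(grid)):
            means[w] = np.nanmean(values[grid.probe_starts[w] : grid.probe_stops[w]])
    return means


def window_mask_flags(
    grid: WindowGrid, masks: MaskSet, genome: GenomeBuild | None = None
) -> np.ndarray:
    """Boolean per-window flag: True where the window intersects any mask.

    A window partially overlapping a mask is masked in full.
    """
    flags = np.zeros(len(grid), dtype=bool)
    for w in range(len(grid)):
        flags[w] = masks.overlaps(
            str(grid.chromosomes[w]), int(grid.starts[w]), int(grid.ends[w])
        )
    return flags


def _autosome_window_index(
    grid: WindowGrid, mask_flags: np.ndarray, genome: GenomeBuild | None
) -> np.ndarray:
    keep = ~mask_flags
    if genome is not None:
        sex_names = {c.name for c in genome.chromosomes if c.is_sex}
        keep &= ~np.isin(grid.chromosomes.astype(str), list(sex_names))
    return np.flatnonzero(keep)


def empirical_fpr(
    control_means: np.ndarray,
    thresholds: Thresholds,
) -> tuple[float, float]:
    """Fraction of null control windows called gained / lost.

    ``control_means`` should already be restricted to unmasked autosomal
    windows (a self-control carries no real aberration, so every call is a
    false positive).  Also accepts probe-level values: the definition is
    identical for any null measurement vector.
    """
    x = np.asarray(control_means, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise ValueError("no unmasked windows to estimate FPR from")
    fpr_gain = float(np.mean(x > thresholds.gain_cut))
    fpr_loss = float(np.mean(x < thresholds.loss_cut))
    return fpr_gain, fpr_loss


def calibrate_thresholds(
    control_means: np.ndarray,
    target_fpr_gain: float = 0.005,
    target_fpr_loss: float = 0.007,
) -> Thresholds:
    """Set gain/loss cuts as empirical quantiles of a null control.

    gain_cut is the (1 - target_fpr_gain) quantile and loss_cut the
    target_fpr_loss quantile of the control window means, so with strict
    calling inequalities the empirical FPR at the returned cuts is at most
    the target (quantile guarantee).
    """
    x = np.asarray(control_means, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise ValueError("no unmasked windows to calibrate from")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) control; cannot calibrate")
    if len(x) < 1000:
        logger.warning(
            "calibrating from only %d windows; >= 1000 recommended", len(x)
        )
    gain_cut = float(np.quantile(x, 1.0 - target_fpr_gain, method="higher"))
    loss_cut = float(np.quantile(x, target_fpr_loss, method="lower"))
    # extreme targets (~0.5) can place a quantile on the wrong side of
    # zero; clamp to an epsilon so the sign invariant holds while any
    # realistic target is untouched
    eps = 1e-9
    gain_cut = max(gain_cut, eps)
    loss_cut = min(loss_cut, -eps)
    return Thresholds(gain_cut=gain_cut, loss_cut=loss_cut)


def call_states(
    means: np.ndarray,
    thresholds: Thresholds,
    mask_flags: np.ndarray | None = None,
    sample_id: str = "",
) -> CallTrack:
    """Threshold window means into LOSS/NORMAL/GAIN, overriding with MASKED.

    Cuts are exclusive: a mean exactly at a cut stays NORMAL.  An undefined
    (NaN) mean in an unmasked window is conservatively NORMAL with a logged
    warning.
    """
    means = np.asarray(means, dtype=float)
    states = np.full(len(means), int(CallState.NORMAL), dtype=np.int8)
    defined = ~np.isnan(means)
    states[defined & (means > thresholds.gain_cut)] = int(CallState.GAIN)
    states[defined & (means < thresholds.loss_cut)] = int(CallState.LOSS)
    if mask_flags is not None:
        states[np.asarray(mask_flags, dtype=bool)] = int(CallState.MASKED)
        undefined_unmasked = ~defined & ~np.asarray(mask_flags, dtype=bool)
    else:
        undefined_unmasked = ~defined
    if undefined_unmasked.any():
        logger.warning(
            "%s: %d unmasked windows with undefined mean called NORMAL",
            sample_id or "<track>",
            int(undefined_unmasked.sum()),
        )
    return CallTrack(sample_id=sample_id, states=states, window_means=means)


def call_cohort(
    tracks: Sequence[RatioTrack],
    grid: WindowGrid,
    thresholds: Thresholds,
    mask_flags: np.ndarray,
) -> list[CallTrack]:
    """Call every sample on a shared grid with shared masks."""
    return [
        call_states(window_means(t, grid), thresholds, mask_flags, sample_id=t.sample_id)
        for t in tracks
    ]
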