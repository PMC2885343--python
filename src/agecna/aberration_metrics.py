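"""Per-sample aberration segments and instability summaries.

An aberration is a maximal run of windows sharing a non-NORMAL state on one
chromosome.  The counting rules are: a segment spanning the entire
chromosome contributes one aberration and zero breakpoints; a segment
strictly interior to the chromosome contributes one aberration and two
breakpoints; a segment touching exactly one chromosome end contributes one
breakpoint (the unique consistent extension: one breakpoint per internal
state boundary).  By default a MASKED gap flanked by the same state is
bridged into one segment, so a centromere does not split a single event in
two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from agecna.copynumber_calls import CallState, CallTrack, WindowGrid
from agecna.synthetic_cohort import RatioTrack

__all__ = [
    "AberrationSegment",
    "SampleMetrics",
    "segments_from_calls",
    "count_aberrations_breakpoints",
    "genome_fractions",
    "replicate_r2",
    "compare_group_counts",
]


@dataclass(frozen=True)
class AberrationSegment:
    """A maximal same-direction run of aberrant windows in one sample."""

    sample_id: str
    chromosome: str
    window_start_index: int  # half-open, indices into the grid
    window_end_index: int
    direction: Literal["gain", "loss"]
    whole_chromosome: bool
    touches_start: bool
    touches_end: bool

    @property
    def n_windows(self) -> int:
        return self.window_end_index - self.window_start_index

    @property
    def n_breakpoints(self) -> int:
        if self.whole_chromosome:
            return 0
        if self.touches_start or self.touches_end:
            return 1
        return 2


@dataclass(frozen=True)
class SampleMetrics:
    sample_id: str
    n_aberrations: int
    n_breakpoints: int
    fraction_aberrant: float
    pct_windows_normal: float


def _chromosome_window_ranges(grid: WindowGrid) -> list[tuple[str, int, int]]:
    ranges = []
    chroms = grid.chromosomes
    start = 0
    for w in range(1, len(grid) + 1):
        if w == len(grid) or chroms[w] != chroms[start]:
            ranges.append((str(chroms[start]), start, w))
            start = w
    return ranges


def segments_from_calls(
    calls: CallTrack,
    grid: WindowGrid,
    bridge_masked: bool = True,
) -> list[AberrationSegment]:
    """Extract maximal aberrant runs per chromosome.

    With ``bridge_masked`` (default) a MASKED stretch between two runs of
    the same state joins them into one segment; with it off, MASKED windows
    terminate runs.  MASKED windows at run edges never extend a segment's
    window range beyond its aberrant members.
    """
    states = calls.states
    segments: list[AberrationSegment] = []
    for chrom, lo, hi in _chromosome_window_ranges(grid):
        sub = states[lo:hi]
        unmasked = np.flatnonzero(sub != int(CallState.MASKED))
        runs: list[tuple[int, int, int]] = []  # (state, first, last) in sub coords
        for i in unmasked:
            s = int(sub[i])
            if s == int(CallState.NORMAL):
                continue
            if runs and runs[-1][0] == s:
                prev_last = runs[-1][2]
                between = sub[prev_last + 1 : i]
                gap_ok = len(between) == 0 or (
                    bridge_masked and np.all(between == int(CallState.MASKED))
                )
                if gap_ok:
                    runs[-1] = (s, runs[-1][1], i)
                    continue
            runs.append((s, i, i))
        n_unmasked = len(unmasked)
        for s, first, last in runs:
            covers_all = False
            if n_unmasked > 0:
                # whole-chromosome means every unmasked window on the
                # chromosome is part of this run
                covers_all = first <= unmasked[0] and last >= unmasked[-1]
            touches_start = n_unmasked > 0 and first <= unmasked[0]
            touches_end = n_unmasked > 0 and last >= unmasked[-1]
            segments.append(
                AberrationSegment(
                    sample_id=calls.sample_id,
                    chromosome=chrom,
                    window_start_index=lo + first,
                    window_end_index=lo + last + 1,
                    direction="gain" if s == int(CallState.GAIN) else "loss",
                    whole_chromosome=covers_all,
                    touches_start=touches_start and not covers_all,
                    touches_end=touches_end and not covers_all,
                )
            )
    return segments


def count_aberrations_breakpoints(
    segments: Sequence[AberrationSegment],
) -> tuple[int, int]:
    """Apply the counting rules: one aberration per segment; 0/1/2 breakpoints
    for whole-chromosome / one-end / interior segments."""
    n_ab = len(segments)
    n_bp = sum(seg.n_breakpoints for seg in segments)
    return n_ab, n_bp


def genome_fractions(
    calls: CallTrack,
    grid: WindowGrid,
    weight: Literal["bp", "count"] = "bp",
) -> tuple[float, float]:
    """(fraction_aberrant, pct_windows_normal) over unmasked windows.

    Weighted by window bp length by default; ``weight='count'`` treats each
    window equally.  The two outputs sum to one exactly.
    """
    unmasked = calls.states != int(CallState.MASKED)
    if not unmasked.any():
        raise ValueError("no unmasked windows")
    aberrant = unmasked & (calls.states != int(CallState.NORMAL))
    if weight == "bp":
        w = grid.bp_lengths().astype(float)
        total = w[unmasked].sum()
        frac = float(w[aberrant].sum() / total)
    else:
        frac = float(aberrant.sum() / unmasked.sum())
    return frac, 1.0 - frac


def sample_metrics(
    calls: CallTrack,
    grid: WindowGrid,
    bridge_masked: bool = True,
    weight: Literal["bp", "count"] = "bp",
) -> SampleMetrics:
    segs = segments_from_calls(calls, grid, bridge_masked=bridge_masked)
    n_ab, n_bp = count_aberrations_breakpoints(segs)
    frac, pct_norm = genome_fractions(calls, grid, weight=weight)
    return SampleMetrics(
        sample_id=calls.sample_id,
        n_aberrations=n_ab,
        n_breakpoints=n_bp,
        fraction_aberrant=frac,
        pct_windows_normal=pct_norm,
    )


def replicate_r2(
    track_a: RatioTrack,
    track_b: RatioTrack,
    calls_a: CallTrack,
    calls_b: CallTrack,
    grid: WindowGrid,
) -> float:
    """Squared Pearson correlation between two hybridizations of one tumor.

    Computed over probes lying in windows where at least one of the pair is
    called non-NORMAL (aberrant loci are what replicate concordance is
    about; the all-normal background would inflate agreement with noise).
    """
    either_aberrant = np.flatnonzero(
        np.isin(calls_a.states, (int(CallState.GAIN), int(CallState.LOSS)))
        | np.isin(calls_b.states, (int(CallState.GAIN), int(CallState.LOSS)))
    )
    probe_idx: list[int] = []
    for w in either_aberrant:
        probe_idx.extend(range(int(grid.probe_starts[w]), int(grid.probe_stops[w])))
    xa = track_a.values[probe_idx]
    xb = track_b.values[probe_idx]
    ok = ~np.isnan(xa) & ~np.isnan(xb)
    if ok.sum() < 3:
        raise ValueError("no aberrant loci shared by the pair; r^2 undefined")
    r, _ = stats.pearsonr(xa[ok], xb[ok])
    return float(r * r)


def compare_group_counts(
    metrics_by_sample: Sequence[SampleMetrics],
    labels: Sequence[str],
    method: Literal["mannwhitney", "ttest"] = "mannwhitney",
) -> dict[str, float]:
    """Two-sided two-sample test per instability metric between groups.

    Mann-Whitney U by default (exact p where sample sizes allow, i.e. no
    ties and both n <= 8, else scipy's asymptotic fallback); a Student
    t-test is available via ``method``.  A metric constant across both
    groups yields p = 1.
    """
    if len(metrics_by_sample) != len(labels):
        raise ValueError("metrics and labels length mismatch")
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    out: dict[str, float] = {}
    for attr, key in [
        ("n_aberrations", "p_aberrations"),
        ("n_breakpoints", "p_breakpoints"),
        ("fraction_aberrant", "p_fraction"),
    ]:
        x = np.array([getattr(m, attr) for m, g in zip(metrics_by_sample, labels) if g == groups[0]], dtype=float)
        y = np.array([getattr(m, attr) for m, g in zip(metrics_by_sample, labels) if g == groups[1]], dtype=float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError("both groups must be non-empty")
        if np.ptp(np.concatenate([x, y])) == 0:
            out[key] = 1.0
            continue
        if method == "mannwhitney":
            _, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        else:
            _, p = stats.ttest_ind(x, y, equal_var=True)
        out[key] = float(min(p, 1.0))
    return out
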