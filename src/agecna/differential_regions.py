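"""Per-window Fisher-exact contrast between the two patient groups.

For every unmasked window two 2x2 tables are tested: patients with a gain
versus without (per group), and patients with a loss versus without.  Runs
of consecutive significant same-direction windows merge into candidate
regions carrying the arithmetic mean of their member p-values; regions
straddling a centromere mask are discarded as likely technical.  Within a
region the smallest region of overlap (SRO) is the minimal window
sub-interval shared by the greatest number of enriched-group carriers.

``fisher_2x2`` computes the two-sided p exactly in integer arithmetic: it
sums the hypergeometric probabilities of every table with the observed
margins that is no more probable than the observed table, and divides once
at the end, so no floating-point comparison can misclassify a tied table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Literal, Sequence

import numpy as np

from agecna.copynumber_calls import CallState, CallTrack, WindowGrid
from agecna.genome_model import GenomeBuild, MaskSet

__all__ = [
    "WindowTest",
    "DifferentialRegion",
    "ExclusionPolicy",
    "fisher_2x2",
    "test_all_windows",
    "merge_regions",
    "find_sro",
    "summarize_genome_significant_fraction",
]


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    n1, n2, k = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or k == 0 or b + d == 0:
        return 1.0
    obs = comb(n1, a) * comb(n2, c)
    num = 0
    for i in range(max(0, k - n2), min(k, n1) + 1):
        w = comb(n1, i) * comb(n2, k - i)
        if w <= obs:
            num += w
    return min(1.0, num / comb(n1 + n2, k))


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Uses the sum-of-small-p rule (every table with the observed margins
    whose hypergeometric probability does not exceed the observed table's
    contributes), evaluated in exact integer arithmetic.  Tables with an
    empty margin return p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"cell counts must be non-negative integers, got {(a, b, c, d)}")
    return _fisher_cached(int(a), int(b), int(c), int(d))


@dataclass(frozen=True)
class WindowTest:
    """One direction's 2x2 test at one window."""

    window: int
    direction: Literal["gain", "loss"]
    n_aberrant_early: int
    n_early: int
    n_aberrant_late: int
    n_late: int
    p: float


@dataclass(frozen=True)
class ExclusionPolicy:
    alpha: float = 0.05
    drop_mask_adjacent: bool = True  # drop regions intersecting centromere masks

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class DifferentialRegion:
    chromosome: str
    start: int
    end: int
    direction: Literal["gain", "loss"]
    avg_p: float
    n_windows: int
    window_indices: tuple[int, ...]
    enriched_group: Literal["early", "late"]
    sro_start: int = -1
    sro_end: int = -1
    sro_carriers_early: int = 0
    sro_carriers_late: int = 0


def _direction_state(direction: str) -> int:
    return int(CallState.GAIN) if direction == "gain" else int(CallState.LOSS)


def test_all_windows(
    calls_by_sample: Sequence[CallTrack],
    labels: Sequence[str],
) -> list[WindowTest]:
    """Fisher tests (gain vs no-gain and loss vs no-loss) per unmasked window."""
    if len(calls_by_sample) != len(labels):
        raise ValueError("calls and labels length mismatch")
    n_windows = {len(c.states) for c in calls_by_sample}
    if len(n_windows) != 1:
        raise ValueError("samples called on different grids")
    labels = list(labels)
    early = np.array([g == "early" for g in labels])
    late = np.array([g == "late" for g in labels])
    if not early.any() or not late.any():
        raise ValueError("need at least one sample per group")
    states = np.stack([c.states for c in calls_by_sample])  # samples x windows
    n_early, n_late = int(early.sum()), int(late.sum())
    tests: list[WindowTest] = []
    masked = np.all(states == int(CallState.MASKED), axis=0)
    for w in range(states.shape[1]):
        if masked[w]:
            continue
        col = states[:, w]
        for direction in ("gain", "loss"):
            sval = _direction_state(direction)
            a = int(np.sum(early & (col == sval)))
            c = int(np.sum(late & (col == sval)))
            p = fisher_2x2(a, n_early - a, c, n_late - c)
            tests.append(
                WindowTest(
                    window=w,
                    direction=direction,  # type: ignore[arg-type]
                    n_aberrant_early=a,
                    n_early=n_early,
                    n_aberrant_late=c,
                    n_late=n_late,
                    p=p,
                )
            )
    return tests


def merge_regions(
    tests: Sequence[WindowTest],
    policy: ExclusionPolicy,
    grid: WindowGrid,
    masks: MaskSet | None = None,
) -> list[DifferentialRegion]:
    """Merge consecutive significant same-direction windows into regions.

    avg_p is the unweighted mean of member-window p-values.  When a mask
    set is supplied and ``drop_mask_adjacent`` is on, a region whose bp
    span intersects a centromere mask is discarded.
    """
    regions: list[DifferentialRegion] = []
    for direction in ("gain", "loss"):
        sig = sorted(
            (t for t in tests if t.direction == direction and t.p < policy.alpha),
            key=lambda t: t.window,
        )
        run: list[WindowTest] = []
        for t in sig:
            if run and (
                t.window != run[-1].window + 1
                or grid.chromosomes[t.window] != grid.chromosomes[run[-1].window]
            ):
                regions.append(_finalize_region(run, direction, grid))
                run = []
            run.append(t)
        if run:
            regions.append(_finalize_region(run, direction, grid))
    if masks is not None and policy.drop_mask_adjacent:
        cen = [m for m in masks.intervals if m.reason == "centromere"]
        regions = [
            r
            for r in regions
            if not any(
                m.chromosome == r.chromosome and m.start < r.end and r.start < m.end
                for m in cen
            )
        ]
    regions.sort(key=lambda r: (str(r.chromosome), r.start, r.direction))
    return regions


def _finalize_region(
    run: list[WindowTest], direction: str, grid: WindowGrid
) -> DifferentialRegion:
    w0, w1 = run[0].window, run[-1].window
    # enrichment direction from pooled carrier frequencies over the run
    f_early = sum(t.n_aberrant_early for t in run) / (run[0].n_early * len(run))
    f_late = sum(t.n_aberrant_late for t in run) / (run[0].n_late * len(run))
    return DifferentialRegion(
        chromosome=str(grid.chromosomes[w0]),
        start=int(grid.starts[w0]),
        end=int(grid.ends[w1]),
        direction=direction,  # type: ignore[arg-type]
        avg_p=float(np.mean([t.p for t in run])),
        n_windows=len(run),
        window_indices=tuple(t.window for t in run),
        enriched_group="early" if f_early >= f_late else "late",
    )


def _run_arrays(
    states_row: np.ndarray, windows: Sequence[int], sval: int, bridge_masked: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per region-window run id and run length for one sample.

    Runs are maximal stretches of the target state along the grid (MASKED
    gaps bridged by default); run length counts the aberrant windows of the
    run, not bridged gaps.  Windows outside any run get id -1.
    """
    n = len(states_row)
    run_id = np.full(n, -1, dtype=int)
    run_len = np.zeros(n, dtype=int)
    rid = -1
    k = 0
    while k < n:
        if states_row[k] == sval:
            rid += 1
            j = k
            length = 0
            last_hit = k
            while j < n:
                if states_row[j] == sval:
                    length += 1
                    last_hit = j
                    j += 1
                elif bridge_masked and states_row[j] == int(CallState.MASKED):
                    j += 1
                else:
                    break
            run_id[k : last_hit + 1] = rid
            run_len[k : last_hit + 1] = length
            k = last_hit + 1
        else:
            k += 1
    return run_id[list(windows)], run_len[list(windows)]


def find_sro(
    calls_by_sample: Sequence[CallTrack],
    labels: Sequence[str],
    region: DifferentialRegion,
    grid: WindowGrid,
    min_carrier_run: int = 2,
) -> DifferentialRegion:
    """Locate the smallest region of overlap inside a differential region.

    Scans every window sub-interval of the region and keeps the one whose
    full extent is aberrant (in the region's direction) in the greatest
    number of enriched-group samples.  Because carrier count can only drop
    as an interval grows, ties on the count are broken toward the LARGEST
    bp extent (then leftmost): the SRO is the full stretch over which the
    maximal carrier overlap is sustained, not an arbitrary single window
    within it.  A sample counts as covering a sub-interval only through an
    aberrant run of at least ``min_carrier_run`` windows (capped at the
    region length), so an isolated false-positive window cannot hijack the
    overlap.  Returns the region with SRO fields filled in.
    """
    if region.n_windows == 0:
        raise ValueError("empty region")
    windows = list(region.window_indices)
    sval = _direction_state(region.direction)
    states = np.stack([c.states for c in calls_by_sample])
    lab = np.asarray(list(labels))
    enriched = lab == region.enriched_group
    n_samples = states.shape[0]
    m = len(windows)
    # restrict run computation to the region's chromosome so a run can
    # never bleed across a chromosome boundary
    chrom_idx = np.flatnonzero(grid.chromosomes == region.chromosome)
    lo = int(chrom_idx[0])
    local_windows = [w - lo for w in windows]
    run_id = np.empty((n_samples, m), dtype=int)
    run_len = np.empty((n_samples, m), dtype=int)
    for s in range(n_samples):
        run_id[s], run_len[s] = _run_arrays(
            states[s, chrom_idx], local_windows, sval
        )
    need = min(min_carrier_run, m)
    best = None  # (carriers, bp, -start) maximization key
    best_ij = (0, 0)
    for i in range(m):
        for j in range(i, m):
            covers = (
                (run_id[:, i] >= 0)
                & (run_id[:, i] == run_id[:, j])
                & (run_len[:, i] >= need)
            )
            n_enriched = int(np.sum(covers & enriched))
            bp = int(grid.ends[windows[j]] - grid.starts[windows[i]])
            key = (n_enriched, bp, -int(grid.starts[windows[i]]))
            if best is None or key > best:
                best = key
                best_ij = (i, j)
    i, j = best_ij
    sub = (
        (run_id[:, i] >= 0) & (run_id[:, i] == run_id[:, j]) & (run_len[:, i] >= need)
    )
    return DifferentialRegion(
        chromosome=region.chromosome,
        start=region.start,
        end=region.end,
        direction=region.direction,
        avg_p=region.avg_p,
        n_windows=region.n_windows,
        window_indices=region.window_indices,
        enriched_group=region.enriched_group,
        sro_start=int(grid.starts[windows[i]]),
        sro_end=int(grid.ends[windows[j]]),
        sro_carriers_early=int(np.sum(sub & (lab == "early"))),
        sro_carriers_late=int(np.sum(sub & (lab == "late"))),
    )


def summarize_genome_significant_fraction(
    regions: Sequence[DifferentialRegion],
    genome: GenomeBuild,
    masks: MaskSet | None = None,
) -> float:
    """Percentage of the unmasked autosomal genome covered by regions.

    Regions must be disjoint (they are, by construction of merge_regions
    within each direction; overlapping gain and loss regions would double
    count and raise).
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        spans.setdefault(r.chromosome, []).append((r.start, r.end))
    total_region = 0
    for chrom, ivs in spans.items():
        ivs.sort()
        for k in range(1, len(ivs)):
            if ivs[k][0] < ivs[k - 1][1]:
                raise ValueError(f"overlapping regions on {chrom}")
        total_region += sum(e - s for s, e in ivs)
    denom = 0
    for c in genome.autosomes:
        masked_bp = 0
        if masks is not None:
            seen: list[tuple[int, int]] = sorted(
                (m.start, m.end) for m in masks.for_chromosome(c.name)
            )
            merged: list[list[int]] = []
            for s, e in seen:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            masked_bp = sum(e - s for s, e in merged)
        denom += c.length - masked_bp
    if denom == 0:
        raise ValueError("no unmasked autosomal genome")
    return 100.0 * total_region / denom
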