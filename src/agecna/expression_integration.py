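"""Integration of copy-number state with mRNA expression.

Each gene inherits the copy-number state of the windows it overlaps, per
sample.  The dosage-concordance statistic divides the median expression of
the gain (or loss) carriers by the median expression of the copy-normal
samples, on the positive linear scale; a gene is concordant for gain when
the ratio is at least 1.5 and concordant for loss when it is below 0.75.
Concordant genes falling inside a differential region of the matching
direction and showing a significant group difference in expression
(independent-samples t-test on the median-centered log view) make the
candidate shortlist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from agecna.copynumber_calls import CallState, CallTrack, WindowGrid
from agecna.differential_regions import DifferentialRegion
from agecna.synthetic_cohort import ExpressionMatrix

__all__ = [
    "IntegrationRecord",
    "gene_states",
    "expression_ratio",
    "concordance_flags",
    "restrict_to_regions",
    "group_expression_test",
    "shortlist",
    "integrate",
]

logger = logging.getLogger(__name__)

GAIN_RATIO_THRESHOLD = 1.5
LOSS_RATIO_THRESHOLD = 0.75


@dataclass(frozen=True)
class IntegrationRecord:
    gene_id: str
    ratio_gain: float  # NaN when undefined (no gain carriers / no normals)
    ratio_loss: float
    n_gain: int
    n_loss: int
    n_normal: int
    concordant_gain: bool = False
    concordant_loss: bool = False
    in_significant_region: bool = False
    group_p: float = float("nan")
    shortlisted: bool = False


def gene_states(
    genes: pd.DataFrame,
    calls_by_sample: Sequence[CallTrack],
    grid: WindowGrid,
) -> pd.DataFrame:
    """Per-(gene, sample) copy-number state from overlapping windows.

    If all overlapped unmasked windows agree the gene takes that state; on
    disagreement it takes the state of the window containing the gene
    midpoint; if every overlapped window is masked the gene is MASKED.
    Returns a genes x samples frame of CallState ints.
    """
    sample_ids = [c.sample_id for c in calls_by_sample]
    states = np.stack([c.states for c in calls_by_sample])  # samples x windows
    out = np.empty((len(genes), len(sample_ids)), dtype=np.int8)
    gchrom = genes["chrom"].to_numpy()
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    chrom_windows = {
        chrom: np.flatnonzero(grid.chromosomes == chrom)
        for chrom in pd.unique(grid.chromosomes)
    }
    for gi in range(len(genes)):
        widx = chrom_windows.get(gchrom[gi], np.empty(0, dtype=int))
        hit = widx[(grid.starts[widx] < gend[gi]) & (gstart[gi] < grid.ends[widx])]
        if len(hit) == 0:
            raise ValueError(
                f"gene {genes['gene_id'].iloc[gi]} overlaps no window"
            )
        mid = (gstart[gi] + gend[gi]) // 2
        inside = hit[(grid.starts[hit] <= mid) & (mid < grid.ends[hit])]
        mid_w = int(inside[0]) if len(inside) else int(hit[np.argmin(np.abs((grid.starts[hit] + grid.ends[hit]) // 2 - mid))])
        for si in range(len(sample_ids)):
            vals = states[si, hit]
            unmasked = vals[vals != int(CallState.MASKED)]
            if len(unmasked) == 0:
                out[gi, si] = int(CallState.MASKED)
            elif np.all(unmasked == unmasked[0]):
                out[gi, si] = unmasked[0]
            else:
                out[gi, si] = states[si, mid_w]
    return pd.DataFrame(out, index=genes["gene_id"].to_numpy(), columns=sample_ids)


def expression_ratio(
    gene_id: str,
    expr: ExpressionMatrix,
    gene_state_row: pd.Series,
) -> tuple[float, float, int, int, int]:
    """Median-ratio dosage statistic for one gene.

    Returns (ratio_gain, ratio_loss, n_gain, n_loss, n_normal); a ratio is
    NaN when its carrier class, or the normal class, is empty.
    """
    levels = expr.linear.loc[gene_id]
    st = gene_state_row.reindex(levels.index)
    gain = levels[st == int(CallState.GAIN)]
    loss = levels[st == int(CallState.LOSS)]
    normal = levels[st == int(CallState.NORMAL)]
    if (levels <= 0).any():
        raise ValueError(f"{gene_id}: non-positive linear expression")
    if len(normal) == 0:
        # fully masked genes are silently undefined; otherwise warn
        if len(gain) or len(loss):
            logger.warning("%s: no copy-normal samples; ratios undefined", gene_id)
        return float("nan"), float("nan"), len(gain), len(loss), 0
    med_norm = float(normal.median())
    rg = float(gain.median() / med_norm) if len(gain) else float("nan")
    rl = float(loss.median() / med_norm) if len(loss) else float("nan")
    return rg, rl, len(gain), len(loss), len(normal)


def concordance_flags(
    record: IntegrationRecord,
    gain_threshold: float = GAIN_RATIO_THRESHOLD,
    loss_threshold: float = LOSS_RATIO_THRESHOLD,
) -> IntegrationRecord:
    """Set dosage-concordance flags: gain inclusive (>= 1.5), loss strict (< 0.75)."""
    cg = bool(not np.isnan(record.ratio_gain) and record.ratio_gain >= gain_threshold)
    cl = bool(not np.isnan(record.ratio_loss) and record.ratio_loss < loss_threshold)
    return replace(record, concordant_gain=cg, concordant_loss=cl)


def restrict_to_regions(
    records: Sequence[IntegrationRecord],
    regions: Sequence[DifferentialRegion],
    genes: pd.DataFrame,
) -> list[IntegrationRecord]:
    """Flag genes intersecting a differential region of their concordant direction."""
    coords = genes.set_index("gene_id")
    out = []
    for rec in records:
        chrom = coords.at[rec.gene_id, "chrom"]
        s, e = int(coords.at[rec.gene_id, "start"]), int(coords.at[rec.gene_id, "end"])
        flag = False
        for r in regions:
            if r.chromosome != chrom or not (r.start < e and s < r.end):
                continue
            if (r.direction == "gain" and rec.concordant_gain) or (
                r.direction == "loss" and rec.concordant_loss
            ):
                flag = True
                break
        out.append(replace(rec, in_significant_region=flag))
    return out


def group_expression_test(
    gene_id: str,
    expr: ExpressionMatrix,
    labels: Sequence[str],
    welch: bool = False,
) -> float:
    """Two-sided independent-samples t-test on centered log expression.

    Classic equal-variance t by default; Welch optionally.  A gene with
    zero variance in both groups returns p = 1.
    """
    centered = expr.centered_log().loc[gene_id]
    lab = np.asarray(list(labels))
    x = centered.to_numpy()[lab == "early"]
    y = centered.to_numpy()[lab == "late"]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need >= 2 samples")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        logger.warning("%s: constant expression in both groups", gene_id)
        return 1.0
    _, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(p)


def shortlist(
    records: Sequence[IntegrationRecord],
    alpha: float = 0.05,
) -> list[IntegrationRecord]:
    """Select candidate genes: concordant, in a matching region, group p < alpha.

    Output sorted by increasing p, then by expression-ratio extremity
    (largest gain ratio or smallest loss ratio first), then gene id.
    """
    chosen = []
    for rec in records:
        ok = (
            (rec.concordant_gain or rec.concordant_loss)
            and rec.in_significant_region
            and not np.isnan(rec.group_p)
            and rec.group_p < alpha
        )
        chosen.append(replace(rec, shortlisted=ok))

    def extremity(r: IntegrationRecord) -> float:
        vals = []
        if r.concordant_gain and not np.isnan(r.ratio_gain):
            vals.append(r.ratio_gain)
        if r.concordant_loss and not np.isnan(r.ratio_loss):
            vals.append(1.0 / r.ratio_loss)
        return max(vals) if vals else 0.0

    short = [r for r in chosen if r.shortlisted]
    short.sort(key=lambda r: (r.group_p, -extremity(r), r.gene_id))
    return short


def integrate(
    genes: pd.DataFrame,
    expr: ExpressionMatrix,
    calls_by_sample: Sequence[CallTrack],
    grid: WindowGrid,
    regions: Sequence[DifferentialRegion],
    labels: Sequence[str],
    alpha: float = 0.05,
    gain_threshold: float = GAIN_RATIO_THRESHOLD,
    loss_threshold: float = LOSS_RATIO_THRESHOLD,
    welch: bool = False,
) -> tuple[list[IntegrationRecord], list[IntegrationRecord]]:
    """Run the full integration for every annotated gene with expression data.

    Returns (all records with flags and p-values, the sorted shortlist).
    """
    common = genes[genes["gene_id"].isin(expr.genes)].reset_index(drop=True)
    gstates = gene_states(common, calls_by_sample, grid)
    records = []
    for gid in common["gene_id"]:
        rg, rl, ng, nl, nn = expression_ratio(gid, expr, gstates.loc[gid])
        rec = IntegrationRecord(
            gene_id=gid, ratio_gain=rg, ratio_loss=rl,
            n_gain=ng, n_loss=nl, n_normal=nn,
        )
        rec = concordance_flags(rec, gain_threshold, loss_threshold)
        records.append(rec)
    records = restrict_to_regions(records, regions, common)
    records = [
        replace(rec, group_p=group_expression_test(rec.gene_id, expr, labels, welch))
        if rec.in_significant_region
        else rec
        for rec in records
    ]
    short = shortlist(records, alpha=alpha)
    short_ids = {r.gene_id for r in short}
    records = [replace(r, shortlisted=r.gene_id in short_ids) for r in records]
    return records, short
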