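"""File I/O for every format the pipeline touches.

Probe ratio tables, expression matrices and sample metadata are TSV;
per-sample calls travel as SEG (1-based inclusive coordinates, the de facto
exchange format for segmented copy-number data); genes, masks, truth and
differential regions are BED (0-based half-open).  All writers format
floats with 6 significant digits and a fixed column order so outputs are
byte-for-byte reproducible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from agecna.copynumber_calls import CallState, CallTrack, WindowGrid
from agecna.differential_regions import DifferentialRegion
from agecna.synthetic_cohort import ExpressionMatrix, ProbeMap, RatioTrack

__all__ = [
    "MISSING_TOKEN",
    "read_probe_table",
    "write_probe_table",
    "write_seg",
    "read_seg",
    "read_gene_bed",
    "write_gene_bed",
    "write_regions_bed",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
]

MISSING_TOKEN = "NA"
VALID_GROUPS = ("early", "late")
VALID_SEX = ("female", "male")


def _fmt(x: float) -> str:
    return MISSING_TOKEN if np.isnan(x) else f"{x:.6g}"


# ---------------------------------------------------------------- probe table

def write_probe_table(
    path: str | Path, probe_map: ProbeMap, tracks: Sequence[RatioTrack]
) -> None:
    with open(path, "w") as fh:
        cols = ["chrom", "start", "end", "probe_id"] + [t.sample_id for t in tracks]
        fh.write("\t".join(cols) + "\n")
        for i in range(len(probe_map)):
            row = [
                str(probe_map.chromosomes[i]),
                str(int(probe_map.starts[i])),
                str(int(probe_map.ends[i])),
                str(probe_map.probe_ids[i]),
            ] + [_fmt(t.values[i]) for t in tracks]
            fh.write("\t".join(row) + "\n")


def read_probe_table(path: str | Path) -> tuple[ProbeMap, list[RatioTrack]]:
    """Parse a probe ratio table; missing cells (``NA``) become NaN.

    Probes must be sorted with strictly increasing starts per chromosome;
    the first offending row is named in the error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=[MISSING_TOKEN])
    required = ["chrom", "start", "end", "probe_id"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"{path}: first columns must be {required}")
    sample_cols = list(df.columns[4:])
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns")
    for chrom, sub in df.groupby("chrom", sort=False):
        bad = np.flatnonzero(np.diff(sub["start"].to_numpy()) <= 0)
        if len(bad):
            row = sub.index[bad[0] + 1] + 2  # 1-based incl. header
            raise ValueError(f"{path}: probes not sorted on {chrom} at row {row}")
    for col in sample_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"{path}: non-numeric ratio in column {col!r} at row {bad[0] + 2}"
            )
    starts = df["start"].to_numpy(dtype=int)
    pm = ProbeMap(
        chromosomes=df["chrom"].to_numpy(dtype=object),
        starts=starts,
        ends=df["end"].to_numpy(dtype=int),
        probe_ids=df["probe_id"].to_numpy(dtype=object),
        spacing=float(np.mean(np.diff(starts)[np.diff(starts) > 0])) if len(starts) > 1 else 1.0,
    )
    tracks = [
        RatioTrack(sample_id=col, values=df[col].to_numpy(dtype=float))
        for col in sample_cols
    ]
    return pm, tracks


# ------------------------------------------------------------------------ SEG

_SEG_HEADER = "Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean"

_STATE_BY_NAME = {s.name: int(s) for s in CallState}


def write_seg(path: str | Path, calls: Sequence[CallTrack], grid: WindowGrid) -> None:
    """Write per-sample window runs as SEG rows (1-based inclusive).

    Consecutive windows sharing a state collapse into one row whose
    Segment_Mean is the probe-weighted mean of member window means; the
    state name is appended as a trailing ``State`` column so the file
    round-trips exactly.
    """
    with open(path, "w") as fh:
        fh.write(_SEG_HEADER + "\tState\n")
        for ct in calls:
            if len(ct.states) != len(grid):
                raise ValueError(f"{ct.sample_id}: calls do not match grid")
            w = 0
            while w < len(grid):
                state = ct.states[w]
                chrom = grid.chromosomes[w]
                j = w
                while (
                    j + 1 < len(grid)
                    and ct.states[j + 1] == state
                    and grid.chromosomes[j + 1] == chrom
                ):
                    j += 1
                n_probes = int(grid.probe_stops[j] - grid.probe_starts[w])
                seg_means = ct.window_means[w : j + 1]
                weights = (grid.probe_stops - grid.probe_starts)[w : j + 1]
                ok = ~np.isnan(seg_means)
                mean = (
                    float(np.average(seg_means[ok], weights=weights[ok]))
                    if ok.any()
                    else float("nan")
                )
                fh.write(
                    f"{ct.sample_id}\t{chrom}\t{int(grid.starts[w]) + 1}\t"
                    f"{int(grid.ends[j])}\t{n_probes}\t{_fmt(mean)}\t"
                    f"{CallState(int(state)).name}\n"
                )
                w = j + 1


def read_seg(path: str | Path, grid: WindowGrid) -> list[CallTrack]:
    """Read a SEG file written by :func:`write_seg` back onto its grid."""
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str}, na_values=[MISSING_TOKEN])
    calls: list[CallTrack] = []
    for sid, sub in df.groupby("Sample", sort=False):
        states = np.full(len(grid), int(CallState.NORMAL), dtype=np.int8)
        means = np.full(len(grid), np.nan)
        for _, row in sub.iterrows():
            start0 = int(row["Start"]) - 1
            end = int(row["End"])
            hit = np.flatnonzero(
                (grid.chromosomes == row["Chromosome"])
                & (grid.starts >= start0)
                & (grid.ends <= end)
            )
            states[hit] = _STATE_BY_NAME[str(row["State"])]
            means[hit] = row["Segment_Mean"]
        calls.append(CallTrack(sample_id=str(sid), states=states, window_means=means))
    return calls


# ------------------------------------------------------------------------ BED

def read_gene_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id"], dtype={"chrom": str},
    )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: empty or inverted gene interval")
    return df


def write_gene_bed(path: str | Path, genes: pd.DataFrame) -> None:
    genes[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_regions_bed(path: str | Path, regions: Sequence[DifferentialRegion]) -> None:
    """BED with name = direction|avg_p|earlyCarriers/lateCarriers|enriched group."""
    with open(path, "w") as fh:
        for r in regions:
            name = (
                f"{r.direction}|p={_fmt(r.avg_p)}|"
                f"{r.sro_carriers_early}/{r.sro_carriers_late}|{r.enriched_group}"
            )
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{name}\n")
            if r.sro_start >= 0:
                fh.write(
                    f"{r.chromosome}\t{r.sro_start}\t{r.sro_end}\t"
                    f"SRO:{name}\n"
                )


def read_regions_bed(path: str | Path) -> list[DifferentialRegion]:
    """Read back a regions BED written by :func:`write_regions_bed`.

    SRO rows (name prefixed ``SRO:``) are folded into their parent region.
    """
    regions: list[DifferentialRegion] = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name = line.rstrip("\n").split("\t")
            is_sro = name.startswith("SRO:")
            body = name[4:] if is_sro else name
            direction, p_part, carriers, group = body.split("|")
            ce, cl = (int(x) for x in carriers.split("/"))
            if is_sro:
                parent = regions[-1]
                regions[-1] = DifferentialRegion(
                    chromosome=parent.chromosome, start=parent.start, end=parent.end,
                    direction=parent.direction, avg_p=parent.avg_p,
                    n_windows=parent.n_windows, window_indices=parent.window_indices,
                    enriched_group=parent.enriched_group,
                    sro_start=int(start), sro_end=int(end),
                    sro_carriers_early=ce, sro_carriers_late=cl,
                )
            else:
                regions.append(
                    DifferentialRegion(
                        chromosome=chrom, start=int(start), end=int(end),
                        direction=direction,  # type: ignore[arg-type]
                        avg_p=float(p_part.removeprefix("p=")),
                        n_windows=0, window_indices=(),
                        enriched_group=group,  # type: ignore[arg-type]
                        sro_carriers_early=ce, sro_carriers_late=cl,
                    )
                )
    return regions


# ----------------------------------------------------------- expression, meta

def write_expression(path: str | Path, expr: ExpressionMatrix) -> None:
    out = expr.linear.map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float))


def write_metadata(
    path: str | Path,
    sample_ids: Sequence[str],
    groups: Sequence[str],
    sexes: Sequence[str] | None = None,
) -> None:
    sexes = sexes or ["female"] * len(sample_ids)
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\tsex\n")
        for s, g, x in zip(sample_ids, groups, sexes):
            fh.write(f"{s}\t{g}\t{x}\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = set(df["group"]) - set(VALID_GROUPS)
    if bad:
        raise ValueError(
            f"{path}: unknown group label(s) {sorted(bad)}; expected {VALID_GROUPS}"
        )
    if "sex" in df.columns:
        bad = set(df["sex"].dropna()) - set(VALID_SEX)
        if bad:
            raise ValueError(f"{path}: unknown sex value(s) {sorted(bad)}")
    return df


def check_sample_concordance(
    track_ids: Sequence[str],
    metadata: pd.DataFrame,
    expr: ExpressionMatrix | None = None,
) -> None:
    """Raise if the ratio table, metadata and expression matrix disagree."""
    meta_ids = set(metadata["sample_id"])
    missing = set(track_ids) - meta_ids
    if missing:
        raise ValueError(f"samples absent from metadata: {sorted(missing)}")
    if expr is not None:
        missing = set(expr.samples) - meta_ids
        if missing:
            raise ValueError(
                f"expression samples absent from metadata: {sorted(missing)}"
            )
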