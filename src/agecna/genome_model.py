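"""Reference genome skeleton and exclusion masks.

Copy-number analysis on tiling arrays is unreliable in a few stereotyped
places: telomeric ends and pericentromeric DNA are rich in repeats, the
short arms of acrocentric chromosomes carry rDNA rather than unique
sequence, and sex chromosomes are confounded whenever tumor and reference
sex differ.  This module owns the genome geometry (chromosome sizes,
centromere intervals, acrocentric and sex flags) and derives the mask
intervals that every downstream module consults before calling, counting or
testing a window.

Coordinates are 0-based half-open throughout; exports follow each file
format's own convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ChromosomeSpec",
    "GenomeBuild",
    "MaskInterval",
    "MaskSet",
    "build_masks",
    "toy_genome",
    "read_genome_table",
    "write_genome_table",
]

#: two windows of 10 probes at ~6 kb spacing
DEFAULT_TELOMERE_PAD = 120_000

MASK_REASONS = ("centromere", "telomere", "acrocentric_p", "sex")


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: length, centromere interval and reliability flags."""

    name: str
    length: int
    centromere_start: int
    centromere_end: int
    acrocentric: bool = False
    is_sex: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.centromere_start < self.centromere_end < self.length):
            raise ValueError(
                f"{self.name}: centromere [{self.centromere_start}, "
                f"{self.centromere_end}) must lie strictly inside (0, {self.length})"
            )
        if self.acrocentric and self.centromere_start > self.length // 2:
            raise ValueError(
                f"{self.name}: acrocentric chromosome must have a proximal centromere"
            )


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosomes plus the telomere pad applied at each end."""

    chromosomes: tuple[ChromosomeSpec, ...]
    telomere_pad: int = DEFAULT_TELOMERE_PAD

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if self.telomere_pad < 0:
            raise ValueError("telomere_pad must be >= 0")
        for c in self.chromosomes:
            if 2 * self.telomere_pad > c.length:
                raise ValueError(
                    f"telomere_pad {self.telomere_pad} exceeds half of {c.name} "
                    f"(length {c.length})"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def autosomes(self) -> tuple[ChromosomeSpec, ...]:
        return tuple(c for c in self.chromosomes if not c.is_sex)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


@dataclass(frozen=True)
class MaskInterval:
    chromosome: str
    start: int
    end: int
    reason: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad mask interval [{self.start}, {self.end})")
        if self.reason not in MASK_REASONS:
            raise ValueError(f"unknown mask reason {self.reason!r}")


@dataclass(frozen=True)
class MaskSet:
    """Excluded intervals, half-open, grouped by chromosome on demand."""

    intervals: tuple[MaskInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))

    def for_chromosome(self, name: str) -> list[MaskInterval]:
        return [m for m in self.intervals if m.chromosome == name]

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        """True if [start, end) intersects any mask on the chromosome."""
        return any(
            m.start < end and start < m.end for m in self.for_chromosome(chromosome)
        )

    def to_bed(self) -> str:
        """BED text with the mask reason in the name column."""
        buf = io.StringIO()
        for m in self.intervals:
            buf.write(f"{m.chromosome}\t{m.start}\t{m.end}\t{m.reason}\n")
        return buf.getvalue()


def build_masks(genome: GenomeBuild) -> MaskSet:
    """Derive the full exclusion geometry for a genome.

    Per chromosome: two telomere pads and the centromere interval; the whole
    p-arm (everything proximal to the centromere) for acrocentric
    chromosomes; the entire chromosome for sex chromosomes.
    """
    intervals: list[MaskInterval] = []
    pad = genome.telomere_pad
    for c in genome.chromosomes:
        if c.is_sex:
            intervals.append(MaskInterval(c.name, 0, c.length, "sex"))
            continue
        if pad > 0:
            intervals.append(MaskInterval(c.name, 0, pad, "telomere"))
            intervals.append(MaskInterval(c.name, c.length - pad, c.length, "telomere"))
        intervals.append(
            MaskInterval(c.name, c.centromere_start, c.centromere_end, "centromere")
        )
        if c.acrocentric:
            intervals.append(MaskInterval(c.name, 0, c.centromere_start, "acrocentric_p"))
    return MaskSet(tuple(intervals))


def toy_genome(
    n_chrom: int,
    chrom_length: int = 10_000_000,
    seed: int = 0,
    telomere_pad: int = DEFAULT_TELOMERE_PAD,
    include_sex: bool = False,
    acrocentric: Sequence[str] = (),
) -> GenomeBuild:
    """Deterministic small genome for simulation and tests.

    Builds ``n_chrom`` equal-length autosomes named chr1..chrN with
    centromeres near mid-chromosome (seeded jitter of up to 10% of the
    length), optionally followed by full-size chrX and chrY flagged as sex
    chromosomes.  Chromosome names listed in ``acrocentric`` get a proximal
    centromere and the acrocentric flag.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    rng = np.random.default_rng(seed)
    cen_width = max(2, chrom_length // 50)
    chroms: list[ChromosomeSpec] = []
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    if include_sex:
        names += ["chrX", "chrY"]
    for name in names:
        is_sex = name in ("chrX", "chrY")
        acro = name in acrocentric
        if acro:
            mid = int(chrom_length * 0.15)
        else:
            jitter = int(rng.integers(-chrom_length // 10, chrom_length // 10 + 1))
            mid = chrom_length // 2 + jitter
        start = max(1, mid - cen_width // 2)
        end = min(chrom_length - 1, start + cen_width)
        chroms.append(
            ChromosomeSpec(
                name=name,
                length=chrom_length,
                centromere_start=start,
                centromere_end=end,
                acrocentric=acro,
                is_sex=is_sex,
            )
        )
    return GenomeBuild(tuple(chroms), telomere_pad=telomere_pad)


_GENOME_HEADER = "name\tlength\tcentromere_start\tcentromere_end\tacrocentric\tis_sex"


def write_genome_table(genome: GenomeBuild, path: str | Path) -> None:
    """Write the genome spec as TSV (one chromosome per row)."""
    lines = [_GENOME_HEADER]
    for c in genome.chromosomes:
        lines.append(
            f"{c.name}\t{c.length}\t{c.centromere_start}\t{c.centromere_end}"
            f"\t{int(c.acrocentric)}\t{int(c.is_sex)}"
        )
    lines.append(f"#telomere_pad={genome.telomere_pad}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genome_table(path: str | Path) -> GenomeBuild:
    pad = DEFAULT_TELOMERE_PAD
    chroms: list[ChromosomeSpec] = []
    text = Path(path).read_text()
    for i, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#telomere_pad="):
            pad = int(line.split("=", 1)[1])
            continue
        if i == 0 and line.startswith("name\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"{path}: malformed genome row {i + 1}: {line!r}")
        chroms.append(
            ChromosomeSpec(
                name=parts[0],
                length=int(parts[1]),
                centromere_start=int(parts[2]),
                centromere_end=int(parts[3]),
                acrocentric=bool(int(parts[4])),
                is_sex=bool(int(parts[5])),
            )
        )
    return GenomeBuild(tuple(chroms), telomere_pad=pad)
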