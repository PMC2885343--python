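"""Synthetic aCGH cohorts with planted copy-number truth.

Emulates a NimbleGen-style whole-genome tiling experiment: a probe map at a
mean spacing of ~6 kb, per-sample normalized log2-ratio tracks for a
two-group tumor cohort (defaults 23 early-onset vs 17 late-onset samples),
technical control hybridizations (self-self and female-vs-male), and a
gene-by-sample expression matrix with cis dosage coupling at the planted
loci.  Every generator records full ground truth so recovery can be scored
exactly.

The default probe noise is calibrated so that 10-probe window means exceed
the +0.1 log2 threshold in ~0.5% of null windows, the regime reported for
the real technical control; see :data:`DEFAULT_NOISE_SD`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from agecna.genome_model import GenomeBuild

__all__ = [
    "ProbeMap",
    "RatioTrack",
    "TruthCNA",
    "CohortConfig",
    "ExpressionMatrix",
    "DEFAULT_NOISE_SD",
    "make_probe_map",
    "simulate_cohort",
    "simulate_control_pair",
    "simulate_expression",
    "make_gene_annotation",
]

# Probe sd such that a 10-probe window mean has P(mean > 0.1) = 0.005 under
# the null: 0.1 * sqrt(10) / Phi^-1(0.995) ~= 0.1228.
DEFAULT_NOISE_SD = float(0.1 * np.sqrt(10) / norm.isf(0.005))

#: |log2 ratio| shift applied to X/Y probes in the female-vs-male control,
#: matching a one-copy difference attenuated as on real arrays.
SEX_CONTROL_SHIFT = 0.4


@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic probes: parallel arrays sorted by chromosome then start."""

    chromosomes: np.ndarray  # dtype object/str, one per probe
    starts: np.ndarray  # int
    ends: np.ndarray  # int
    probe_ids: np.ndarray  # str
    spacing: float  # mean inter-probe distance (bp)

    def __post_init__(self) -> None:
        n = len(self.starts)
        if not (len(self.chromosomes) == len(self.ends) == len(self.probe_ids) == n):
            raise ValueError("probe arrays must have equal length")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        # sortedness within chromosome
        for chrom in pd.unique(self.chromosomes):
            s = self.starts[self.chromosomes == chrom]
            if np.any(np.diff(s) <= 0):
                raise ValueError(f"probes on {chrom} are not strictly increasing")

    def __len__(self) -> int:
        return len(self.starts)

    def chromosome_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chromosomes == chrom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chromosomes,
                "start": self.starts,
                "end": self.ends,
                "probe_id": self.probe_ids,
            }
        )


@dataclass
class RatioTrack:
    """One sample's normalized log2 ratios aligned to a ProbeMap.

    ``values`` may contain NaN for missing measurements; everything else
    must be finite.
    """

    sample_id: str
    values: np.ndarray
    sex: Literal["female", "male"] = "female"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[~np.isnan(self.values)]
        if not np.all(np.isfinite(finite)):
            raise ValueError(f"{self.sample_id}: non-finite log2 ratios")


@dataclass(frozen=True)
class TruthCNA:
    """A planted aberration: ground truth for recovery scoring."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    direction: Literal["gain", "loss"]
    magnitude: float
    group_specific: bool = False

    def __post_init__(self) -> None:
        if self.direction == "gain" and self.magnitude <= 0:
            raise ValueError("gain magnitude must be positive")
        if self.direction == "loss" and self.magnitude >= 0:
            raise ValueError("loss magnitude must be negative")
        if self.start >= self.end:
            raise ValueError("empty truth interval")


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the simulated two-group cohort."""

    n_early: int = 23
    n_late: int = 17
    shared_cna_rate: float = 2.0  # expected shared events per sample
    early_specific_cna_rate: float = 1.0
    noise_sd: float = DEFAULT_NOISE_SD
    gain_magnitude: float = 0.45
    loss_magnitude: float = -0.45
    event_length: int = 2_000_000  # bp, typical planted event extent
    dosage_effect: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_early < 1 or self.n_late < 1:
            raise ValueError("both groups need at least one sample")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.dosage_effect < 1:
            raise ValueError("dosage_effect must be >= 1")


class ExpressionMatrix:
    """Gene x sample expression on a positive linear scale.

    ``linear`` is the quantile-normalized-style positive matrix used for the
    median-ratio statistic; :meth:`centered_log` gives the log2 view with
    per-gene median centering used for group-difference testing.
    """

    def __init__(self, linear: pd.DataFrame):
        if (linear.values <= 0).any():
            raise ValueError("linear expression values must be positive")
        if linear.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        self.linear = linear

    @property
    def genes(self) -> pd.Index:
        return self.linear.index

    @property
    def samples(self) -> pd.Index:
        return self.linear.columns

    def centered_log(self) -> pd.DataFrame:
        logged = np.log2(self.linear)
        return logged.sub(logged.median(axis=1), axis=0)


def make_probe_map(
    genome: GenomeBuild,
    spacing: int = 6000,
    jitter: float = 0.25,
    seed: int = 0,
    probe_length: int = 50,
) -> ProbeMap:
    """Tile every chromosome with probes at a mean spacing.

    Probe starts advance by ``spacing`` plus seeded uniform jitter of up to
    ``jitter * spacing`` in either direction; ``jitter=0`` gives exactly
    regular spacing.  Probe count per chromosome is floor(length / spacing).
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    starts: list[int] = []
    for c in genome.chromosomes:
        n = c.length // spacing
        if n == 0:
            raise ValueError(f"spacing {spacing} exceeds {c.name} length {c.length}")
        base = np.arange(n, dtype=float) * spacing
        if jitter > 0:
            offs = rng.uniform(-jitter * spacing, jitter * spacing, size=n)
        else:
            offs = np.zeros(n)
        pos = np.clip(base + offs, 0, c.length - probe_length - 1)
        pos = np.sort(pos).astype(int)
        # enforce strict increase after clipping/rounding
        pos = np.maximum.accumulate(pos + np.arange(n) * 0)
        for k in range(1, n):
            if pos[k] <= pos[k - 1]:
                pos[k] = pos[k - 1] + 1
        chroms.extend([c.name] * n)
        starts.extend(pos.tolist())
    starts_arr = np.asarray(starts, dtype=int)
    chrom_arr = np.asarray(chroms, dtype=object)
    ids = np.asarray([f"P{i:07d}" for i in range(len(starts_arr))], dtype=object)
    return ProbeMap(
        chromosomes=chrom_arr,
        starts=starts_arr,
        ends=starts_arr + probe_length,
        probe_ids=ids,
        spacing=float(spacing),
    )


def _probe_signal(probe_map: ProbeMap, events: Sequence[TruthCNA]) -> np.ndarray:
    """Sum of event magnitudes over probes each event covers."""
    signal = np.zeros(len(probe_map))
    for ev in events:
        idx = probe_map.chromosome_index(ev.chromosome)
        inside = idx[
            (probe_map.starts[idx] >= ev.start) & (probe_map.starts[idx] < ev.end)
        ]
        signal[inside] += ev.magnitude
    return signal


def _sample_events(
    rng: np.random.Generator,
    genome: GenomeBuild,
    sample_id: str,
    n_events: int,
    config: CohortConfig,
    group_specific: bool,
) -> list[TruthCNA]:
    events = []
    autosomes = genome.autosomes
    for _ in range(n_events):
        c = autosomes[rng.integers(len(autosomes))]
        length = int(rng.exponential(config.event_length)) + config.event_length // 4
        length = min(length, c.length - 2)
        start = int(rng.integers(0, c.length - length))
        gain = rng.random() < 0.5
        events.append(
            TruthCNA(
                sample_id=sample_id,
                chromosome=c.name,
                start=start,
                end=start + length,
                direction="gain" if gain else "loss",
                magnitude=config.gain_magnitude if gain else config.loss_magnitude,
                group_specific=group_specific,
            )
        )
    return events


@dataclass(frozen=True)
class PlantedLocus:
    """A recurrent locus planted with fixed per-group penetrance."""

    chromosome: str
    start: int
    end: int
    direction: Literal["gain", "loss"]
    magnitude: float
    n_early_carriers: int
    n_late_carriers: int


def simulate_cohort(
    genome: GenomeBuild,
    probe_map: ProbeMap,
    config: CohortConfig,
    planted_loci: Sequence[PlantedLocus] = (),
) -> tuple[list[RatioTrack], list[str], list[TruthCNA]]:
    """Simulate per-sample log2-ratio tracks for a two-group cohort.

    Each sample receives Poisson-distributed random background events
    (shared regime in both groups, plus extra events in early samples at
    ``early_specific_cna_rate``), and each ``PlantedLocus`` is planted in
    exactly the stated number of carriers per group (carriers chosen by the
    seeded RNG).  Probe value = sum of overlapping event magnitudes +
    Gaussian(0, noise_sd).

    Returns (tracks, group labels aligned to tracks, all truth events).
    """
    rng = np.random.default_rng(config.seed)
    sample_ids = [f"E{i + 1:02d}" for i in range(config.n_early)] + [
        f"L{i + 1:02d}" for i in range(config.n_late)
    ]
    labels = ["early"] * config.n_early + ["late"] * config.n_late

    truth: list[TruthCNA] = []
    events_by_sample: dict[str, list[TruthCNA]] = {s: [] for s in sample_ids}

    for sid, group in zip(sample_ids, labels):
        n_shared = rng.poisson(config.shared_cna_rate)
        evs = _sample_events(rng, genome, sid, n_shared, config, group_specific=False)
        events_by_sample[sid].extend(evs)

    for locus in planted_loci:
        early_ids = sample_ids[: config.n_early]
        late_ids = sample_ids[config.n_early :]
        carriers = list(
            rng.choice(early_ids, size=locus.n_early_carriers, replace=False)
        ) + list(rng.choice(late_ids, size=locus.n_late_carriers, replace=False))
        for sid in carriers:
            events_by_sample[sid].append(
                TruthCNA(
                    sample_id=sid,
                    chromosome=locus.chromosome,
                    start=locus.start,
                    end=locus.end,
                    direction=locus.direction,
                    magnitude=locus.magnitude,
                    group_specific=True,
                )
            )

    tracks: list[RatioTrack] = []
    for sid in sample_ids:
        evs = events_by_sample[sid]
        truth.extend(evs)
        signal = _probe_signal(probe_map, evs)
        if config.noise_sd > 0:
            signal = signal + rng.normal(0.0, config.noise_sd, size=len(probe_map))
        tracks.append(RatioTrack(sample_id=sid, values=signal))
    return tracks, labels, truth


def simulate_control_pair(
    probe_map: ProbeMap,
    noise_sd: float = DEFAULT_NOISE_SD,
    kind: Literal["self_self", "female_vs_male"] = "self_self",
    seed: int = 0,
    sex_shift: float = SEX_CONTROL_SHIFT,
) -> RatioTrack:
    """Simulate a technical control hybridization.

    ``self_self`` is pure measurement noise.  ``female_vs_male`` adds a
    one-copy gain signal on every chrX probe and a one-copy loss on every
    chrY probe, emulating a female pool hybridized against a male pool.
    """
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        values = rng.normal(0.0, noise_sd, size=len(probe_map))
    else:
        values = np.zeros(len(probe_map))
    if kind == "female_vs_male":
        x_idx = probe_map.chromosome_index("chrX")
        y_idx = probe_map.chromosome_index("chrY")
        if len(x_idx) == 0 or len(y_idx) == 0:
            raise ValueError("female_vs_male control requires chrX and chrY probes")
        values[x_idx] += sex_shift
        values[y_idx] -= sex_shift
    elif kind != "self_self":
        raise ValueError(f"unknown control kind {kind!r}")
    return RatioTrack(sample_id=f"control_{kind}", values=values)


def make_gene_annotation(
    genome: GenomeBuild,
    n_genes: int,
    seed: int = 0,
    gene_length: int = 30_000,
) -> pd.DataFrame:
    """Scatter non-overlapping gene intervals uniformly over autosomes.

    Returns a BED-like frame (chrom, start, end, gene_id) sorted by
    position.
    """
    rng = np.random.default_rng(seed)
    autosomes = genome.autosomes
    lengths = np.array([c.length for c in autosomes], dtype=float)
    probs = lengths / lengths.sum()
    rows = []
    for i in range(n_genes):
        c = autosomes[rng.choice(len(autosomes), p=probs)]
        start = int(rng.integers(0, c.length - gene_length))
        rows.append((c.name, start, start + gene_length, f"G{i:05d}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def simulate_expression(
    genes: pd.DataFrame,
    truth: Sequence[TruthCNA],
    sample_ids: Sequence[str],
    dosage_effect: float = 1.8,
    noise_sd_expr: float = 0.25,
    decoupled_fraction: float = 0.0,
    baseline: float = 100.0,
    seed: int = 0,
    coupled_genes: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Simulate a gene x sample expression matrix with cis dosage coupling.

    Each gene's baseline is log-normal around ``baseline``.  For a coupled
    gene, samples carrying a gain overlapping the gene have their
    expectation multiplied by ``dosage_effect`` and loss carriers divided by
    it; a ``decoupled_fraction`` of genes (chosen by the seeded RNG) ignores
    copy number entirely, or the coupled set can be fixed explicitly via
    ``coupled_genes``.  Multiplicative log-normal noise with log2-scale sd
    ``noise_sd_expr`` is applied per measurement.
    """
    if dosage_effect < 1:
        raise ValueError("dosage_effect must be >= 1")
    rng = np.random.default_rng(seed)
    gene_ids = genes["gene_id"].to_numpy()
    n_genes, n_samples = len(gene_ids), len(sample_ids)
    if coupled_genes is not None:
        coupled = np.isin(gene_ids, list(coupled_genes))
    else:
        coupled = rng.random(n_genes) >= decoupled_fraction

    # per-(gene, sample) net copy state from truth events overlapping the gene
    state = np.zeros((n_genes, n_samples), dtype=int)
    sample_pos = {s: j for j, s in enumerate(sample_ids)}
    gchrom = genes["chrom"].to_numpy()
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    for ev in truth:
        if ev.sample_id not in sample_pos:
            continue
        j = sample_pos[ev.sample_id]
        hit = (gchrom == ev.chromosome) & (gstart < ev.end) & (ev.start < gend)
        state[hit, j] += 1 if ev.direction == "gain" else -1

    base = baseline * 2.0 ** rng.normal(0.0, 1.0, size=n_genes)
    expect = np.tile(base[:, None], (1, n_samples)).astype(float)
    factor = np.power(dosage_effect, np.sign(state))
    factor[~coupled, :] = 1.0
    expect *= factor
    values = expect * 2.0 ** rng.normal(0.0, noise_sd_expr, size=expect.shape)
    frame = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                         columns=list(sample_ids))
    return ExpressionMatrix(frame)
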