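"""End-to-end orchestration: simulate -> call -> metrics -> diff -> integrate.

Every stage reads and writes plain files in standard formats (TSV/SEG/BED)
so each can also be run standalone on user-provided data.  A run is fully
determined by its :class:`RunConfig` (YAML-serializable) and seed; the
manifest records the config hash and a checksum per output so reruns can be
verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from agecna import array_io
from agecna.aberration_metrics import compare_group_counts, sample_metrics
from agecna.copynumber_calls import (
    Thresholds,
    build_windows,
    calibrate_thresholds,
    call_cohort,
    window_mask_flags,
    window_means,
)
from agecna.differential_regions import (
    ExclusionPolicy,
    find_sro,
    merge_regions,
    summarize_genome_significant_fraction,
    test_all_windows,
)
from agecna.expression_integration import integrate
from agecna.genome_model import build_masks, toy_genome, write_genome_table
from agecna.synthetic_cohort import (
    CohortConfig,
    PlantedLocus,
    make_gene_annotation,
    make_probe_map,
    simulate_cohort,
    simulate_control_pair,
    simulate_expression,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_all", "default_demo_config"]


@dataclass
class RunConfig:
    outdir: str = "agecna_run"
    seed: int = 0
    # genome / probes
    n_chrom: int = 6
    chrom_length: int = 30_000_000
    telomere_pad: int = 120_000
    probe_spacing: int = 6000
    probes_per_window: int = 10
    # cohort
    n_early: int = 23
    n_late: int = 17
    shared_cna_rate: float = 2.0
    early_specific_cna_rate: float = 0.0
    noise_sd: float | None = None  # None -> calibrated default
    planted_loci: list[dict[str, Any]] = field(default_factory=list)
    # calling
    gain_cut: float = 0.1
    loss_cut: float = -0.1
    calibrate: bool = False
    target_fpr_gain: float = 0.005
    target_fpr_loss: float = 0.007
    # differential testing
    alpha: float = 0.05
    # expression / integration
    run_integration: bool = True
    n_genes: int = 600
    dosage_effect: float = 1.8
    decoupled_fraction: float = 0.3
    noise_sd_expr: float = 0.25
    gain_ratio_threshold: float = 1.5
    loss_ratio_threshold: float = 0.75

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    checksums: dict[str, str]
    stage_seconds: dict[str, float]
    counters: dict[str, float]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violated invariants; empty means runnable."""
    problems = []
    if config.n_early < 1:
        problems.append("n_early must be >= 1")
    if config.n_late < 1:
        problems.append("n_late must be >= 1")
    if not config.loss_cut < 0 < config.gain_cut:
        problems.append("need loss_cut < 0 < gain_cut")
    if not 0 < config.alpha < 1:
        problems.append("alpha must lie in (0, 1)")
    if config.probe_spacing < 1:
        problems.append("probe_spacing must be >= 1")
    if config.probe_spacing > config.chrom_length:
        problems.append("probe_spacing exceeds chromosome length")
    if 2 * config.telomere_pad > config.chrom_length:
        problems.append("telomere_pad exceeds half a chromosome")
    if config.dosage_effect < 1:
        problems.append("dosage_effect must be >= 1")
    if not 0 <= config.decoupled_fraction <= 1:
        problems.append("decoupled_fraction must lie in [0, 1]")
    for i, d in enumerate(config.planted_loci):
        missing = {"chromosome", "start", "end", "direction"} - set(d)
        if missing:
            problems.append(f"planted_loci[{i}] missing keys {sorted(missing)}")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _planted(config: RunConfig) -> list[PlantedLocus]:
    out = []
    for d in config.planted_loci:
        direction = d["direction"]
        mag = d.get("magnitude", 0.45 if direction == "gain" else -0.45)
        out.append(
            PlantedLocus(
                chromosome=d["chromosome"],
                start=int(d["start"]),
                end=int(d["end"]),
                direction=direction,
                magnitude=float(mag),
                n_early_carriers=int(d.get("n_early_carriers", 14)),
                n_late_carriers=int(d.get("n_late_carriers", 2)),
            )
        )
    return out


def default_demo_config(outdir: str = "agecna_demo", seed: int = 0) -> RunConfig:
    """Small bundled demo: 4 chromosomes, two planted early-enriched loci."""
    return RunConfig(
        outdir=outdir,
        seed=seed,
        n_chrom=4,
        chrom_length=20_000_000,
        planted_loci=[
            {"chromosome": "chr2", "start": 4_000_000, "end": 7_000_000,
             "direction": "loss", "n_early_carriers": 14, "n_late_carriers": 2},
            {"chromosome": "chr3", "start": 12_000_000, "end": 14_500_000,
             "direction": "gain", "n_early_carriers": 10, "n_late_carriers": 1},
        ],
        n_genes=400,
    )


def run_all(config: RunConfig) -> RunManifest:
    """Execute the full pipeline and write all stage outputs plus a manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counters: dict[str, float] = {}
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    # ---- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    genome = toy_genome(
        config.n_chrom, config.chrom_length, seed=sub[0],
        telomere_pad=config.telomere_pad, include_sex=True,
    )
    probe_map = make_probe_map(genome, spacing=config.probe_spacing, seed=sub[0])
    noise_sd = config.noise_sd
    cohort_kwargs = dict(
        n_early=config.n_early,
        n_late=config.n_late,
        shared_cna_rate=config.shared_cna_rate,
        early_specific_cna_rate=config.early_specific_cna_rate,
        dosage_effect=config.dosage_effect,
        seed=sub[1],
    )
    if noise_sd is not None:
        cohort_kwargs["noise_sd"] = noise_sd
    cohort_cfg = CohortConfig(**cohort_kwargs)
    tracks, labels, truth = simulate_cohort(
        genome, probe_map, cohort_cfg, planted_loci=_planted(config)
    )
    control = simulate_control_pair(
        probe_map, noise_sd=cohort_cfg.noise_sd, kind="self_self", seed=sub[2]
    )
    write_genome_table(genome, out / "genome.tsv")
    array_io.write_probe_table(out / "probes.tsv", probe_map, tracks)
    array_io.write_probe_table(out / "control.tsv", probe_map, [control])
    array_io.write_metadata(out / "metadata.tsv", [t.sample_id for t in tracks], labels)
    with open(out / "truth.bed", "w") as fh:
        for ev in truth:
            fh.write(
                f"{ev.chromosome}\t{ev.start}\t{ev.end}\t"
                f"{ev.sample_id}:{ev.direction}:{ev.magnitude:.6g}\n"
            )
    timings["simulate"] = time.perf_counter() - t0

    # ---- call -------------------------------------------------------------
    t0 = time.perf_counter()
    grid = build_windows(probe_map, config.probes_per_window)
    masks = build_masks(genome)
    mask_flags = window_mask_flags(grid, masks)
    if config.calibrate:
        ctrl_means = window_means(control, grid)[~mask_flags]
        thresholds = calibrate_thresholds(
            ctrl_means, config.target_fpr_gain, config.target_fpr_loss
        )
    else:
        thresholds = Thresholds(config.gain_cut, config.loss_cut)
    calls = call_cohort(tracks, grid, thresholds, mask_flags)
    array_io.write_seg(out / "calls.seg", calls, grid)
    counters["windows_total"] = len(grid)
    counters["windows_masked"] = int(mask_flags.sum())
    counters["gain_cut"] = thresholds.gain_cut
    counters["loss_cut"] = thresholds.loss_cut
    timings["call"] = time.perf_counter() - t0

    # ---- metrics ----------------------------------------------------------
    t0 = time.perf_counter()
    metrics = [sample_metrics(c, grid) for c in calls]
    group_p = compare_group_counts(metrics, labels)
    with open(out / "metrics.tsv", "w") as fh:
        fh.write(
            "sample_id\tgroup\tn_aberrations\tn_breakpoints\t"
            "fraction_aberrant\tpct_windows_normal\n"
        )
        for m, g in zip(metrics, labels):
            fh.write(
                f"{m.sample_id}\t{g}\t{m.n_aberrations}\t{m.n_breakpoints}\t"
                f"{m.fraction_aberrant:.6g}\t{m.pct_windows_normal:.6g}\n"
            )
    counters.update({f"metrics_{k}": v for k, v in group_p.items()})
    timings["metrics"] = time.perf_counter() - t0

    # ---- diff -------------------------------------------------------------
    t0 = time.perf_counter()
    tests = test_all_windows(calls, labels)
    policy = ExclusionPolicy(alpha=config.alpha)
    regions = merge_regions(tests, policy, grid, masks)
    regions = [find_sro(calls, labels, r, grid) for r in regions]
    array_io.write_regions_bed(out / "regions.bed", regions)
    with open(out / "windows.tsv", "w") as fh:
        fh.write("window\tchrom\tstart\tend\tdirection\tearly\tn_early\tlate\tn_late\tp\n")
        for t in tests:
            fh.write(
                f"{t.window}\t{grid.chromosomes[t.window]}\t{grid.starts[t.window]}\t"
                f"{grid.ends[t.window]}\t{t.direction}\t{t.n_aberrant_early}\t"
                f"{t.n_early}\t{t.n_aberrant_late}\t{t.n_late}\t{t.p:.6g}\n"
            )
    counters["windows_tested"] = len({t.window for t in tests})
    counters["regions_found"] = len(regions)
    counters["genome_pct_significant"] = summarize_genome_significant_fraction(
        regions, genome, masks
    )
    timings["diff"] = time.perf_counter() - t0

    # ---- integrate --------------------------------------------------------
    if config.run_integration:
        t0 = time.perf_counter()
        genes = make_gene_annotation(genome, config.n_genes, seed=sub[3])
        expr = simulate_expression(
            genes, truth, [t.sample_id for t in tracks],
            dosage_effect=config.dosage_effect,
            noise_sd_expr=config.noise_sd_expr,
            decoupled_fraction=config.decoupled_fraction,
            seed=sub[3],
        )
        array_io.write_gene_bed(out / "genes.bed", genes)
        array_io.write_expression(out / "expression.tsv", expr)
        records, short = integrate(
            genes, expr, calls, grid, regions, labels,
            alpha=config.alpha,
            gain_threshold=config.gain_ratio_threshold,
            loss_threshold=config.loss_ratio_threshold,
        )
        with open(out / "integration.tsv", "w") as fh:
            fh.write(
                "gene_id\tratio_gain\tratio_loss\tn_gain\tn_loss\tn_normal\t"
                "concordant_gain\tconcordant_loss\tin_significant_region\t"
                "group_p\tshortlisted\n"
            )
            for r in records:
                fh.write(
                    f"{r.gene_id}\t{_nafmt(r.ratio_gain)}\t{_nafmt(r.ratio_loss)}\t"
                    f"{r.n_gain}\t{r.n_loss}\t{r.n_normal}\t"
                    f"{int(r.concordant_gain)}\t{int(r.concordant_loss)}\t"
                    f"{int(r.in_significant_region)}\t{_nafmt(r.group_p)}\t"
                    f"{int(r.shortlisted)}\n"
                )
        counters["genes_shortlisted"] = len(short)
        timings["integrate"] = time.perf_counter() - t0

    cfg_hash = hashlib.sha256(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True).encode()
    ).hexdigest()
    checksums = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.suffix in
        (".tsv", ".seg", ".bed")
    }
    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=config.seed,
        checksums=checksums,
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
        counters={k: float(v) for k, v in counters.items()},
    )
    manifest.write(out / "manifest.json")
    for stage, secs in timings.items():
        logger.info("stage %-10s %.2fs", stage, secs)
    return manifest


def _nafmt(x: float) -> str:
    return "NA" if np.isnan(x) else f"{x:.6g}"
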