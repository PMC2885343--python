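import numpy as np
import pytest

from agecna.copynumber_calls import build_windows
from agecna.genome_model import ChromosomeSpec, GenomeBuild, build_masks
from agecna.synthetic_cohort import make_probe_map


@pytest.fixture(scope="session")
def tiny_genome():
    """One 1 Mb chromosome, centromere mid, small telomere pad."""
    chrom = ChromosomeSpec("chr1", 1_000_000, 480_000, 520_000)
    return GenomeBuild((chrom,), telomere_pad=30_000)


@pytest.fixture(scope="session")
def small_genome():
    """Three 2 Mb autosomes plus fully masked sex chromosomes."""
    chroms = [
        ChromosomeSpec(f"chr{i}", 2_000_000, 950_000, 1_050_000) for i in (1, 2, 3)
    ] + [
        ChromosomeSpec("chrX", 2_000_000, 950_000, 1_050_000, is_sex=True),
        ChromosomeSpec("chrY", 2_000_000, 950_000, 1_050_000, is_sex=True),
    ]
    return GenomeBuild(tuple(chroms), telomere_pad=60_000)


@pytest.fixture(scope="session")
def small_probe_map(small_genome):
    return make_probe_map(small_genome, spacing=6000, jitter=0.0, seed=0)


@pytest.fixture(scope="session")
def small_grid(small_probe_map):
    return build_windows(small_probe_map, probes_per_window=10)


@pytest.fixture(scope="session")
def small_masks(small_genome):
    return build_masks(small_genome)
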