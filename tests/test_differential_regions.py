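from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from agecna.copynumber_calls import CallState, CallTrack, build_windows
from agecna.differential_regions import (
    DifferentialRegion,
    ExclusionPolicy,
    fisher_2x2,
    find_sro,
    merge_regions,
    summarize_genome_significant_fraction,
)
from agecna.differential_regions import test_all_windows as window_contrast
from agecna.genome_model import (
    ChromosomeSpec,
    GenomeBuild,
    MaskInterval,
    MaskSet,
    build_masks,
)
from agecna.synthetic_cohort import make_probe_map

G, L, N, M = (
    int(CallState.GAIN),
    int(CallState.LOSS),
    int(CallState.NORMAL),
    int(CallState.MASKED),
)


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p via explicit hypergeometric enumeration."""
    n1, n2, k = a + b, c + d, a + c
    total = comb(n1 + n2, k)
    obs = Fraction(comb(n1, a) * comb(n2, c), total)
    p = Fraction(0)
    for i in range(max(0, k - n2), min(k, n1) + 1):
        w = Fraction(comb(n1, i) * comb(n2, k - i), total)
        if w <= obs:
            p += w
    return float(min(p, Fraction(1)))


def grid_for(n_windows, chrom="chr1"):
    genome = GenomeBuild(
        (ChromosomeSpec(chrom, n_windows * 60_000 + 100, 10, 20),), telomere_pad=0
    )
    pm = make_probe_map(genome, spacing=6000, jitter=0.0)
    return build_windows(pm, 10)


def cohort_calls(state_matrix, n_early):
    """Rows = samples, cols = windows; first n_early rows labelled early."""
    calls = [
        CallTrack(f"s{i}", np.asarray(row, dtype=np.int8), np.zeros(len(row)))
        for i, row in enumerate(state_matrix)
    ]
    labels = ["early"] * n_early + ["late"] * (len(state_matrix) - n_early)
    return calls, labels


class TestFisher:
    def test_published_carrier_tables(self):
        assert round(fisher_2x2(14, 9, 2, 15), 3) == 0.003
        assert round(fisher_2x2(10, 13, 1, 16), 2) == 0.01
        assert round(fisher_2x2(8, 15, 0, 17), 2) == 0.01

    def test_balanced_table_p_one(self):
        assert fisher_2x2(5, 5, 5, 5) == 1.0

    def test_empty_margins_p_one(self):
        assert fisher_2x2(0, 0, 0, 0) == 1.0
        assert fisher_2x2(0, 5, 0, 7) == 1.0
        assert fisher_2x2(5, 0, 7, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(max_examples=300, deadline=None)
    def test_symmetries(self, a, b, c, d):
        p = fisher_2x2(a, b, c, d)
        assert p == fisher_2x2(c, d, a, b)  # group exchange
        assert p == fisher_2x2(b, a, d, c)  # outcome exchange
        assert 0.0 <= p <= 1.0

    @given(
        a=st.integers(0, 10), b=st.integers(0, 10),
        c=st.integers(0, 10), d=st.integers(0, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        assert fisher_2x2(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )

    def test_matches_scipy_on_study_sized_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = int(rng.integers(0, 24)); b = 23 - a
            c = int(rng.integers(0, 18)); d = 17 - c
            _, p_ref = fisher_exact([[a, b], [c, d]])
            assert fisher_2x2(a, b, c, d) == pytest.approx(p_ref, rel=1e-9, abs=1e-12)


class TestWindowTests:
    def test_planted_table_repeats_across_windows(self):
        # 14/23 early vs 2/17 late carry a 5-window loss
        n_windows, n_early, n_late = 5, 23, 17
        mat = []
        for i in range(n_early):
            mat.append([L] * n_windows if i < 14 else [N] * n_windows)
        for i in range(n_late):
            mat.append([L] * n_windows if i < 2 else [N] * n_windows)
        calls, labels = cohort_calls(mat, n_early)
        tests = [t for t in window_contrast(calls, labels) if t.direction == "loss"]
        assert len(tests) == n_windows
        for t in tests:
            assert t.p == pytest.approx(fisher_2x2(14, 9, 2, 15))

    def test_no_aberrations_all_p_one(self):
        calls, labels = cohort_calls([[N, N, N]] * 6, 3)
        assert all(t.p == 1.0 for t in window_contrast(calls, labels))

    def test_fully_masked_windows_skipped(self):
        calls, labels = cohort_calls([[M, G, N]] * 4, 2)
        tested = {t.window for t in window_contrast(calls, labels)}
        assert tested == {1, 2}

    def test_mismatched_grids_rejected(self):
        calls, labels = cohort_calls([[N, N], [N, N, N]], 1)
        with pytest.raises(ValueError, match="grids"):
            window_contrast(calls, labels)

    def test_label_permutation_controls_false_positives(self):
        rng = np.random.default_rng(7)
        n_samples, n_windows = 40, 120
        # exchangeable background: every sample same per-window gain rate
        mat = np.where(rng.random((n_samples, n_windows)) < 0.15, G, N)
        calls, labels = cohort_calls(mat, 23)
        sig = [t for t in window_contrast(calls, labels) if t.p < 0.05]
        # Fisher is conservative on discrete tables: at most ~5% of tests
        assert len(sig) <= 0.05 * 2 * n_windows + 3


class TestRegions:
    def test_avg_p_is_arithmetic_mean(self):
        grid = grid_for(5)
        mat = [[N, L, L, L, N]] * 14 + [[N] * 5] * 9 + [[N] * 5] * 17
        calls, labels = cohort_calls(mat, 23)
        tests = window_contrast(calls, labels)
        regions = merge_regions(tests, ExclusionPolicy(), grid)
        assert len(regions) == 1
        member_p = [t.p for t in tests if t.direction == "loss" and 1 <= t.window <= 3]
        assert regions[0].avg_p == pytest.approx(np.mean(member_p))
        assert regions[0].n_windows == 3
        assert regions[0].enriched_group == "early"

    def test_region_straddling_centromere_dropped(self):
        grid = grid_for(5)
        mat = [[L] * 5] * 14 + [[N] * 5] * 9 + [[N] * 5] * 17
        calls, labels = cohort_calls(mat, 23)
        tests = window_contrast(calls, labels)
        mid = int(grid.starts[2])
        masks = MaskSet((MaskInterval("chr1", mid, mid + 1000, "centromere"),))
        assert merge_regions(tests, ExclusionPolicy(), grid, masks) == []
        no_mask = merge_regions(tests, ExclusionPolicy(), grid)
        assert len(no_mask) == 1

    def test_isolated_significant_window_is_single_window_region(self):
        grid = grid_for(3)
        mat = [[N, G, N]] * 14 + [[N] * 3] * 9 + [[N] * 3] * 17
        calls, labels = cohort_calls(mat, 23)
        regions = merge_regions(window_contrast(calls, labels), ExclusionPolicy(), grid)
        assert len(regions) == 1 and regions[0].n_windows == 1

    def test_regions_disjoint_and_cover_all_significant_windows(self):
        rng = np.random.default_rng(11)
        grid = grid_for(40)
        mat = np.where(rng.random((40, 40)) < 0.2, L, N)
        mat[:23, 10:15] = L  # early-enriched stripe
        calls, labels = cohort_calls(mat, 23)
        tests = window_contrast(calls, labels)
        policy = ExclusionPolicy()
        regions = merge_regions(tests, policy, grid)
        covered = [w for r in regions for w in r.window_indices]
        assert len(covered) == len(set(covered))
        sig = {
            (t.window, t.direction) for t in tests if t.p < policy.alpha
        }
        in_regions = {
            (w, r.direction) for r in regions for w in r.window_indices
        }
        assert sig == in_regions


class TestSro:
    def brute_force_sro(self, calls, labels, region, grid, min_run=2):
        """Independent re-derivation scanning all sub-intervals directly."""
        sval = G if region.direction == "gain" else L
        lab = np.asarray(labels)
        windows = list(region.window_indices)
        chrom_idx = np.flatnonzero(grid.chromosomes == region.chromosome)
        need = min(min_run, len(windows))
        best, best_iv = None, None
        for i in range(len(windows)):
            for j in range(i, len(windows)):
                count = 0
                for s, g in zip(calls, lab):
                    if g != region.enriched_group:
                        continue
                    # run containing the sub-interval, masked windows bridged
                    st_ = [int(s.states[w]) for w in chrom_idx]
                    local = [w - chrom_idx[0] for w in windows]
                    lo, hi = local[i], local[j]
                    if any(
                        st_[w] not in (sval, M) for w in range(lo, hi + 1)
                    ):
                        continue
                    a = lo
                    while a > 0 and st_[a - 1] in (sval, M):
                        a -= 1
                    b = hi
                    while b < len(st_) - 1 and st_[b + 1] in (sval, M):
                        b += 1
                    length = sum(1 for w in range(a, b + 1) if st_[w] == sval)
                    covers_iv = all(
                        st_[w] == sval or st_[w] == M for w in range(lo, hi + 1)
                    ) and any(st_[w] == sval for w in range(lo, hi + 1))
                    if covers_iv and length >= need and st_[lo] != M and st_[hi] != M:
                        count += 1
                bp = int(grid.ends[windows[j]] - grid.starts[windows[i]])
                key = (count, bp, -int(grid.starts[windows[i]]))
                if best is None or key > best:
                    best, best_iv = key, (windows[i], windows[j])
        return best_iv

    def test_shared_core_found(self):
        grid = grid_for(10)
        row_core = [N] * 3 + [L] * 3 + [N] * 4  # windows 3-5
        mat = [row_core] * 14 + [[N] * 10] * 9 + [[N] * 10] * 17
        calls, labels = cohort_calls(mat, 23)
        regions = merge_regions(window_contrast(calls, labels), ExclusionPolicy(), grid)
        r = find_sro(calls, labels, regions[0], grid)
        assert (r.sro_start, r.sro_end) == (int(grid.starts[3]), int(grid.ends[5]))
        assert r.sro_carriers_early == 14
        assert r.sro_carriers_late == 0

    def test_nested_events_short_core_wins(self):
        grid = grid_for(10)
        long_row = [L] * 10
        core_row = [N] * 4 + [L] * 2 + [N] * 4  # windows 4-5
        mat = [long_row] * 8 + [core_row] * 14 + [[N] * 10] + [[N] * 10] * 17
        calls, labels = cohort_calls(mat, 23)
        regions = merge_regions(window_contrast(calls, labels), ExclusionPolicy(), grid)
        assert len(regions) == 1
        r = find_sro(calls, labels, regions[0], grid)
        assert (r.sro_start, r.sro_end) == (int(grid.starts[4]), int(grid.ends[5]))
        assert r.sro_carriers_early == 22
        oracle = self.brute_force_sro(calls, labels, regions[0], grid)
        assert oracle == (4, 5)

    def test_single_window_region_sro_is_that_window(self):
        grid = grid_for(3)
        mat = [[N, G, N]] * 14 + [[N] * 3] * 9 + [[N] * 3] * 17
        calls, labels = cohort_calls(mat, 23)
        regions = merge_regions(window_contrast(calls, labels), ExclusionPolicy(), grid)
        r = find_sro(calls, labels, regions[0], grid)
        assert (r.sro_start, r.sro_end) == (int(grid.starts[1]), int(grid.ends[1]))

    def test_isolated_noise_window_cannot_hijack_sro(self):
        grid = grid_for(10)
        carrier = [N] + [L] * 8 + [N]
        noise = [N] * 5 + [L] + [N] * 4  # single-window call in one more sample
        mat = [carrier] * 14 + [noise] + [[N] * 10] * 8 + [[N] * 10] * 17
        calls, labels = cohort_calls(mat, 23)
        regions = merge_regions(window_contrast(calls, labels), ExclusionPolicy(), grid)
        r = find_sro(calls, labels, regions[0], grid)
        assert (r.sro_start, r.sro_end) == (int(grid.starts[1]), int(grid.ends[8]))
        assert r.sro_carriers_early == 14

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(13)
        grid = grid_for(8)
        for _ in range(10):
            mat = np.where(rng.random((12, 8)) < 0.4, L, N)
            mat[:5, 2:6] = L
            calls, labels = cohort_calls(mat, 7)
            regions = merge_regions(
                window_contrast(calls, labels), ExclusionPolicy(alpha=0.5), grid
            )
            for region in regions:
                if region.direction != "loss":
                    continue
                r = find_sro(calls, labels, region, grid)
                oracle = self.brute_force_sro(calls, labels, region, grid)
                assert (r.sro_start, r.sro_end) == (
                    int(grid.starts[oracle[0]]),
                    int(grid.ends[oracle[1]]),
                )


class TestGenomeFraction:
    def test_no_regions_zero_percent(self):
        genome = GenomeBuild((ChromosomeSpec("chr1", 10**9, 10, 20),), telomere_pad=0)
        assert summarize_genome_significant_fraction([], genome) == 0.0

    def test_simple_arithmetic(self):
        genome = GenomeBuild((ChromosomeSpec("chr1", 10**9, 10, 20),), telomere_pad=0)
        region = DifferentialRegion(
            "chr1", 0, 32_000_000, "loss", 0.01, 1, (0,), "early"
        )
        assert summarize_genome_significant_fraction([region], genome) == pytest.approx(3.2)

    def test_overlapping_regions_rejected(self):
        genome = GenomeBuild((ChromosomeSpec("chr1", 10**9, 10, 20),), telomere_pad=0)
        r1 = DifferentialRegion("chr1", 0, 100, "loss", 0.01, 1, (0,), "early")
        r2 = DifferentialRegion("chr1", 50, 150, "gain", 0.01, 1, (1,), "early")
        with pytest.raises(ValueError, match="overlapping"):
            summarize_genome_significant_fraction([r1, r2], genome)
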