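import numpy as np
import pandas as pd
import pytest

from agecna.copynumber_calls import CallState, CallTrack, build_windows
from agecna.differential_regions import DifferentialRegion
from agecna.expression_integration import (
    IntegrationRecord,
    concordance_flags,
    expression_ratio,
    gene_states,
    group_expression_test,
    integrate,
    restrict_to_regions,
    shortlist,
)
from agecna.genome_model import ChromosomeSpec, GenomeBuild
from agecna.synthetic_cohort import ExpressionMatrix, make_probe_map

G, L, N, M = (
    int(CallState.GAIN),
    int(CallState.LOSS),
    int(CallState.NORMAL),
    int(CallState.MASKED),
)


def grid_for(n_windows):
    genome = GenomeBuild(
        (ChromosomeSpec("chr1", n_windows * 60_000 + 100, 10, 20),), telomere_pad=0
    )
    pm = make_probe_map(genome, spacing=6000, jitter=0.0)
    return build_windows(pm, 10)


def call(states, sid):
    return CallTrack(sid, np.asarray(states, dtype=np.int8), np.zeros(len(states)))


def expr_matrix(data, genes, samples):
    return ExpressionMatrix(
        pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=samples)
    )


class TestGeneStates:
    def test_gene_inside_single_window(self):
        grid = grid_for(3)
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [70_000], "end": [80_000], "gene_id": ["g"]}
        )
        st = gene_states(genes, [call([N, G, N], "s1")], grid)
        assert st.loc["g", "s1"] == G

    def test_conflicting_windows_resolved_by_midpoint(self):
        grid = grid_for(2)
        # gene spans windows 0 and 1; midpoint in window 1 (NORMAL)
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [50_000], "end": [130_000], "gene_id": ["g"]}
        )
        st = gene_states(genes, [call([G, N], "s1")], grid)
        assert st.loc["g", "s1"] == N

    def test_fully_masked_gene_is_masked(self):
        grid = grid_for(2)
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [10_000], "end": [20_000], "gene_id": ["g"]}
        )
        st = gene_states(genes, [call([M, N], "s1")], grid)
        assert st.loc["g", "s1"] == M

    def test_gene_outside_windows_rejected(self):
        grid = grid_for(2)
        genes = pd.DataFrame(
            {"chrom": ["chr9"], "start": [0], "end": [100], "gene_id": ["g"]}
        )
        with pytest.raises(ValueError, match="overlaps no window"):
            gene_states(genes, [call([N, N], "s1")], grid)


class TestRatio:
    def _states(self, states, samples):
        return pd.Series(states, index=samples)

    def test_equal_expression_gives_unit_ratio(self):
        samples = ["a", "b", "c", "d"]
        expr = expr_matrix([[5.0, 5.0, 5.0, 5.0]], ["g"], samples)
        rg, rl, ng, nl, nn = expression_ratio(
            "g", expr, self._states([G, G, N, N], samples)
        )
        assert rg == pytest.approx(1.0)
        assert np.isnan(rl)
        assert (ng, nl, nn) == (2, 0, 2)

    def test_doubled_carriers_give_ratio_two(self):
        samples = ["a", "b", "c", "d"]
        expr = expr_matrix([[10.0, 10.0, 5.0, 5.0]], ["g"], samples)
        rg, _, _, _, _ = expression_ratio(
            "g", expr, self._states([G, G, N, N], samples)
        )
        assert rg == pytest.approx(2.0)

    def test_scale_equivariance(self):
        samples = ["a", "b", "c", "d", "e"]
        vals = np.array([[3.0, 8.0, 5.0, 4.0, 6.0]])
        st = self._states([G, G, N, N, L], samples)
        r1 = expression_ratio("g", expr_matrix(vals, ["g"], samples), st)
        r2 = expression_ratio("g", expr_matrix(vals * 7.3, ["g"], samples), st)
        assert r1[0] == pytest.approx(r2[0])
        assert r1[1] == pytest.approx(r2[1])

    def test_no_normal_samples_undefined(self):
        samples = ["a", "b"]
        expr = expr_matrix([[1.0, 2.0]], ["g"], samples)
        rg, rl, _, _, nn = expression_ratio("g", expr, self._states([G, G], samples))
        assert np.isnan(rg) and np.isnan(rl) and nn == 0


class TestConcordance:
    @pytest.mark.parametrize(
        "ratio_gain,ratio_loss,cg,cl",
        [
            (1.5, np.nan, True, False),   # gain threshold inclusive
            (1.49, np.nan, False, False),
            (np.nan, 0.75, False, False),  # loss threshold strict
            (np.nan, 0.749, False, True),
            (2.0, 0.5, True, True),
            (np.nan, np.nan, False, False),
        ],
    )
    def test_threshold_boundaries(self, ratio_gain, ratio_loss, cg, cl):
        rec = IntegrationRecord("g", ratio_gain, ratio_loss, 1, 1, 2)
        rec = concordance_flags(rec)
        assert (rec.concordant_gain, rec.concordant_loss) == (cg, cl)


class TestRegionsAndShortlist:
    def _genes(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [10, 1000, 5000],
                "end": [100, 1100, 5100],
                "gene_id": ["g1", "g2", "g3"],
            }
        )

    def _region(self, direction="gain", start=0, end=2000):
        return DifferentialRegion(
            "chr1", start, end, direction, 0.01, 3, (0, 1, 2), "early"
        )

    def test_direction_must_match(self):
        recs = [
            IntegrationRecord("g1", 2.0, np.nan, 3, 0, 5, concordant_gain=True),
            IntegrationRecord("g2", np.nan, 0.5, 0, 3, 5, concordant_loss=True),
            IntegrationRecord("g3", 2.0, np.nan, 3, 0, 5, concordant_gain=True),
        ]
        out = restrict_to_regions(recs, [self._region("gain")], self._genes())
        flags = {r.gene_id: r.in_significant_region for r in out}
        # g1 concordant-gain in gain region; g2 concordant-loss only; g3 outside
        assert flags == {"g1": True, "g2": False, "g3": False}

    def test_shortlist_requires_all_criteria(self):
        recs = [
            IntegrationRecord("g1", 2.0, np.nan, 3, 0, 5, concordant_gain=True,
                              in_significant_region=True, group_p=0.01),
            IntegrationRecord("g2", 2.0, np.nan, 3, 0, 5, concordant_gain=True,
                              in_significant_region=False, group_p=0.01),
            IntegrationRecord("g3", 2.0, np.nan, 3, 0, 5, concordant_gain=True,
                              in_significant_region=True, group_p=0.2),
        ]
        short = shortlist(recs)
        assert [r.gene_id for r in short] == ["g1"]

    def test_shortlist_monotone_in_alpha(self):
        recs = [
            IntegrationRecord(f"g{i}", 2.0, np.nan, 3, 0, 5, concordant_gain=True,
                              in_significant_region=True, group_p=p)
            for i, p in enumerate([0.001, 0.01, 0.04, 0.2])
        ]
        sizes = [len(shortlist(recs, alpha=a)) for a in (0.005, 0.05, 0.5)]
        assert sizes == sorted(sizes)

    def test_shortlist_sorted_by_p_then_extremity(self):
        recs = [
            IntegrationRecord("a", 1.6, np.nan, 3, 0, 5, concordant_gain=True,
                              in_significant_region=True, group_p=0.02),
            IntegrationRecord("b", 3.0, np.nan, 3, 0, 5, concordant_gain=True,
                              in_significant_region=True, group_p=0.02),
            IntegrationRecord("c", 1.6, np.nan, 3, 0, 5, concordant_gain=True,
                              in_significant_region=True, group_p=0.001),
        ]
        assert [r.gene_id for r in shortlist(recs)] == ["c", "b", "a"]

    def test_empty_region_list_gives_empty_shortlist(self):
        grid = grid_for(3)
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [70_000], "end": [80_000], "gene_id": ["g"]}
        )
        samples = [f"s{i}" for i in range(6)]
        calls = [call([N, G, N], s) for s in samples[:3]] + [
            call([N, N, N], s) for s in samples[3:]
        ]
        expr = expr_matrix([[9.0, 9.0, 9.0, 3.0, 3.0, 3.0]], ["g"], samples)
        labels = ["early"] * 3 + ["late"] * 3
        records, short = integrate(genes, expr, calls, grid, [], labels)
        assert short == []
        assert records[0].concordant_gain  # ratio 3.0, but no region


class TestGroupTest:
    def test_strong_shift_detected(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(40)]
        labels = ["early"] * 23 + ["late"] * 17
        vals = np.concatenate([rng.normal(8, 0.3, 23), rng.normal(2, 0.3, 17)])
        expr = expr_matrix([np.exp(vals)], ["g"], samples)
        assert group_expression_test("g", expr, labels) < 0.001

    def test_constant_gene_p_one(self):
        samples = [f"s{i}" for i in range(6)]
        expr = expr_matrix([[4.0] * 6], ["g"], samples)
        labels = ["early"] * 3 + ["late"] * 3
        assert group_expression_test("g", expr, labels) == 1.0

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(40)]
        ps = []
        for _ in range(200):
            vals = np.exp(rng.normal(3, 0.5, 40))
            expr = expr_matrix([vals], ["g"], samples)
            labels = list(np.array(["early"] * 23 + ["late"] * 17))
            rng.shuffle(labels)
            ps.append(group_expression_test("g", expr, labels))
        assert np.mean(np.array(ps) < 0.05) < 0.11
        assert np.mean(ps) == pytest.approx(0.5, abs=0.1)

    def test_small_group_rejected(self):
        samples = ["a", "b", "c"]
        expr = expr_matrix([[1.0, 2.0, 3.0]], ["g"], samples)
        with pytest.raises(ValueError, match=">= 2"):
            group_expression_test("g", expr, ["early", "early", "late"])
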