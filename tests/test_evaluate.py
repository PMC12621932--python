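import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _utils import make_matrix
from panelsmith import evaluate
from panelsmith.selection import Panel, PanelLocus


def toy_panel(n=3, length=100, gap=200, contig="c1"):
    loci = []
    pos = 1000
    for i in range(n):
        loci.append(PanelLocus(
            locus_id=f"L{i}", contig=contig, start=pos, end=pos + length,
            core_start=pos + 20, core_end=pos + length - 20, cm=float(i),
            snp_count=0, fwd_seq="A" * 20, rev_seq="C" * 20))
        pos += length + gap
    return Panel(loci)


def aln(rows):
    return pd.DataFrame(rows, columns=["read_id", "contig", "start", "end",
                                       "multimap"])


class TestAssignReads:
    def test_contained_read_assigned(self):
        panel = toy_panel()
        res = evaluate.assign_reads(aln([("r1", "c1", 1010, 1090, 0)]), panel)
        assert res.counts["L0"] == 1
        assert res.tallies["assigned"] == 1

    def test_forty_percent_overlap_unassigned(self):
        panel = toy_panel()
        # read of 100 bp overlapping the locus by 40 bp
        res = evaluate.assign_reads(aln([("r1", "c1", 1060, 1160, 0)]), panel)
        assert res.counts.sum() == 0
        assert res.tallies["off_panel"] == 1

    def test_multimap_excluded_but_tallied(self):
        panel = toy_panel()
        res = evaluate.assign_reads(aln([("r1", "c1", 1010, 1090, 1)]), panel)
        assert res.counts["L0"] == 0
        assert res.tallies["multimap_excluded"] == 1

    def test_malformed_row_rejected(self):
        panel = toy_panel()
        res = evaluate.assign_reads(aln([("r1", "c1", 50, 50, 0)]), panel)
        assert res.tallies["rejected"] == 1

    def test_read_conservation(self):
        rng = np.random.default_rng(0)
        panel = toy_panel(n=5)
        rows = []
        for i in range(200):
            start = int(rng.integers(0, 3000))
            rows.append((f"r{i}", "c1", start, start + int(rng.integers(-10, 150)),
                         int(rng.random() < 0.2)))
        res = evaluate.assign_reads(aln(rows), panel)
        assert sum(res.tallies.values()) == 200


class TestCoverageUniformity:
    def test_uniform_counts(self):
        out = evaluate.coverage_uniformity([10] * 10)
        assert out["top_share"] == pytest.approx(0.1)
        assert out["gini"] == pytest.approx(0.0)

    def test_single_locus_dominates(self):
        out = evaluate.coverage_uniformity([100] + [0] * 9)
        assert out["top_share"] == pytest.approx(1.0)

    def test_gini_closed_form(self):
        out = evaluate.coverage_uniformity([4, 3, 2, 1])
        assert out["gini"] == pytest.approx(0.25)
        assert sorted(out["shares"], reverse=True) == pytest.approx(
            [0.4, 0.3, 0.2, 0.1])

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            evaluate.coverage_uniformity([0, 0])


class TestBalancingFactors:
    def test_at_target_share(self):
        f = evaluate.balancing_factors([10, 10, 10, 10])
        np.testing.assert_allclose(f, 1.0)

    def test_double_share_halved(self):
        f = evaluate.balancing_factors([2, 1, 1]),
        np.testing.assert_allclose(
            evaluate.balancing_factors([2, 1, 1])[0], (1 / 3) / 0.5)

    def test_zero_count_gets_upper_clamp(self):
        f = evaluate.balancing_factors([5, 0, 5], clamp=(0.1, 2.0))
        assert f[1] == 2.0


class TestRarefaction:
    def test_endpoint_exact(self):
        counts = np.array([50, 5, 30])
        curve = evaluate.rarefaction(counts, depths=[85], threshold=10,
                                     replicates=5, seed=0)
        assert curve.mean[0] == curve.observed_proportion
        assert curve.sd[0] == 0.0
        assert curve.observed_proportion == pytest.approx(2 / 3)

    def test_unreachable_threshold(self):
        curve = evaluate.rarefaction([50, 50], depths=[5], threshold=10,
                                     replicates=50, seed=1)
        assert curve.mean[0] == 0.0

    @pytest.mark.parametrize("counts", [(50, 5), (30, 25)])
    def test_matches_hypergeometric_tail(self, counts):
        """Two-locus subsample at depth 20, threshold 10: the mean
        proportion of genotyped loci equals the closed-form hypergeometric
        tails within Monte-Carlo error.  (With counts (50, 5) locus 1 is
        guaranteed >= 15 reads and locus 2 can never reach 10, so the
        value is exact; (30, 25) exercises a genuinely stochastic tail.)"""
        counts = np.array(counts)
        reps = 10_000
        curve = evaluate.rarefaction(counts, depths=[20], threshold=10,
                                     replicates=reps, seed=7)
        total = counts.sum()
        expected = sum(stats.hypergeom.sf(9, total, k, 20) for k in counts) / 2
        mc_sd = max(np.sqrt(expected * (1 - expected) / reps), 1e-12)
        assert abs(curve.mean[0] - expected) <= 4 * mc_sd

    def test_curve_monotone_within_noise(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 60, size=40)
        depths = [100, 300, 600, int(counts.sum())]
        curve = evaluate.rarefaction(counts, depths, threshold=10,
                                     replicates=200, seed=5)
        for i in range(len(depths) - 1):
            slack = 3 * (curve.sd[i] + curve.sd[i + 1]) / np.sqrt(200)
            assert curve.mean[i + 1] >= curve.mean[i] - slack

    def test_depth_beyond_pool_rejected(self):
        with pytest.raises(ValueError, match="extrapolation"):
            evaluate.rarefaction([5, 5], depths=[100], replicates=2, seed=0)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            evaluate.rarefaction([5, 5], depths=[0], replicates=2, seed=0)


class TestSnpsPerAmplicon:
    def test_counts_and_boundaries(self):
        panel = toy_panel()
        l0 = panel.loci[0]
        # 3 in L0, 1 exactly at the half-open end (not counted), 1 off-panel
        m = make_matrix([["0/1"]] * 5,
                        positions=[l0.start, l0.start + 10, l0.end - 1,
                                   l0.end, 5])
        out = evaluate.snps_per_amplicon(m, panel)
        assert out["per_locus"]["L0"] == 3
        assert out["off_panel_variants"] == 2

    def test_empty(self):
        panel = toy_panel()
        m = make_matrix([["0/1"]], positions=[1])
        out = evaluate.snps_per_amplicon(m, panel)
        assert out["per_locus"].sum() == 0


class TestAmpliconSizeStats:
    def test_additive_arithmetic(self):
        loci = [PanelLocus(locus_id=f"L{i}", contig="c1", start=0, end=n,
                           core_start=0, core_end=n, cm=None, snp_count=0,
                           fwd_tail="T" * 60, rev_tail="T" * 71)
                for i, n in enumerate([100, 120, 140])]
        out = evaluate.amplicon_size_stats(Panel(loci))
        assert out["amplicon_min"] == 100
        assert out["amplicon_median"] == 120
        assert out["amplicon_max"] == 140
        assert out["library_min"] == 231
        assert out["library_max"] == 271
        assert out["total_targeted_bp"] == 360

    def test_single_locus(self):
        loci = [PanelLocus(locus_id="L0", contig="c1", start=0, end=90,
                           core_start=0, core_end=90, cm=None, snp_count=0)]
        out = evaluate.amplicon_size_stats(Panel(loci))
        assert out["amplicon_min"] == out["amplicon_max"] == 90

    def test_missing_length_listed(self):
        loci = [PanelLocus(locus_id="bad", contig="c1", start=10, end=10,
                           core_start=0, core_end=0, cm=None, snp_count=0)]
        with pytest.raises(ValueError, match="bad"):
            evaluate.amplicon_size_stats(Panel(loci))


class TestMicrohaplotypes:
    def _panel(self):
        return Panel([PanelLocus(locus_id="L0", contig="c1", start=0, end=100,
                                 core_start=0, core_end=100, cm=None,
                                 snp_count=2)])

    def test_phased_hets(self):
        m = make_matrix([["0|1"], ["1|0"]], positions=[10, 20])
        out = evaluate.extract_microhaplotypes(m, self._panel())
        assert out.iloc[0]["hap1"] == "01"
        assert out.iloc[0]["hap2"] == "10"

    def test_hom_ref_locus(self):
        m = make_matrix([["0|0"], ["0/0"]], positions=[10, 20])
        out = evaluate.extract_microhaplotypes(m, self._panel())
        assert out.iloc[0]["hap1"] == "00"

    def test_unphased_het_is_null(self):
        m = make_matrix([["0|1"], ["0/1"]], positions=[10, 20])
        out = evaluate.extract_microhaplotypes(m, self._panel())
        assert out.iloc[0]["hap1"] is None
        assert out.iloc[0]["reason"] == "unphased heterozygote"

    def test_missing_call_is_null(self):
        m = make_matrix([["0|1"], ["./."]], positions=[10, 20])
        out = evaluate.extract_microhaplotypes(m, self._panel())
        assert out.iloc[0]["reason"] == "missing call"


class TestBalancingImprovesUniformity:
    def test_rebalancing_reduces_cv(self, sim_bundle):
        """Applying measured balancing factors to the simulated primer
        pool reduces the coefficient of variation of per-locus counts in
        >=95 of 100 seeded trials."""
        from dataclasses import replace as dc_replace

        from panelsmith import simulate
        from panelsmith.selection import Panel, PanelLocus

        wins = 0
        loci = [PanelLocus(locus_id=f"L{i}", contig="c1", start=i * 500,
                           end=i * 500 + 120, core_start=i * 500,
                           core_end=i * 500 + 120, cm=None, snp_count=0)
                for i in range(20)]
        for seed in range(100):
            cfg = simulate.SimulationConfig(seed=seed, read_total=20_000)
            panel = Panel([dc_replace(l, balancing_factor=1.0) for l in loci])
            _, counted, totals = simulate.simulate_read_table(panel, cfg)
            factors = evaluate.balancing_factors(totals.to_numpy())
            panel2 = Panel([dc_replace(l, balancing_factor=f)
                            for l, f in zip(loci, factors)])
            _, _, totals2 = simulate.simulate_read_table(panel2, cfg)
            cv1 = totals.std() / totals.mean()
            cv2 = totals2.std() / totals2.mean()
            if cv2 < cv1:
                wins += 1
        assert wins >= 95
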