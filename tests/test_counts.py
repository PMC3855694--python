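"""Counting against the reference, symmetric merging, summaries and QC."""

import numpy as np
import pytest

from methkit import (
    CytosineRecord,
    GenomicFeature,
    MappedRead,
    count_methylation,
    coverage_density_correlation,
    level_confidence_interval,
    merge_symmetric_cpgs,
    methylome_summary,
    region_levels,
    simulate_bs_reads,
)
from ._oracles import wilson_interval


def read_at(pos, base, strand="+"):
    return MappedRead("chr1", pos, pos + 1, strand, f"r{pos}{base}{strand}", base, [40], "l")


class TestCountMethylation:
    def test_plus_strand_cpg_counts(self):
        ref = {"chr1": "ACGT"}
        reads = [read_at(1, b) for b in "CCCT"]
        records = count_methylation(reads, ref)
        by_pos = {r.pos: r for r in records}
        assert by_pos[1].meth == 3 and by_pos[1].total == 4
        assert by_pos[1].level == pytest.approx(0.75)
        assert by_pos[1].context == "CpG" and by_pos[1].strand == "+"
        assert by_pos[2].strand == "-" and by_pos[2].context == "CpG"

    def test_mismatch_bases_ignored(self):
        records = count_methylation([read_at(1, "G")], {"chr1": "ACGT"})
        assert {r.pos: r.total for r in records}[1] == 0

    def test_minus_strand_counts(self):
        records = count_methylation(
            [read_at(2, "G", "-"), read_at(2, "A", "-")], {"chr1": "ACGT"}
        )
        r = {x.pos: x for x in records}[2]
        assert (r.meth, r.total) == (1, 2)

    def test_context_assignment(self):
        # CAG: C..G with one base between -> CHG; CAT -> CHH
        records = count_methylation([], {"chr1": "CAGCATCG"})
        ctx = {r.pos: r.context for r in records if r.strand == "+"}
        assert ctx[0] == "CHG" and ctx[3] == "CHH" and ctx[6] == "CpG"

    def test_read_past_reference_end(self):
        bad = MappedRead("chr1", 2, 6, "+", "r", "ACGT", [40] * 4, "l")
        with pytest.raises(ValueError, match="past reference"):
            count_methylation([bad], {"chr1": "ACGT"})

    def test_recount_matches_simulated_levels(self):
        """Counted levels agree with the generating level within 3 sigma."""
        ref = "AT" + "CG" * 40 + "AT"
        levels = {i: 0.7 for i, b in enumerate(ref) if b in "CG"}
        reads = simulate_bs_reads(ref, n_reads=600, read_len=40, levels=levels, seed=9)
        records = count_methylation(reads, {"chr1": ref})
        for r in records:
            if r.total >= 20:
                sigma = np.sqrt(0.7 * 0.3 / r.total)
                assert abs(r.level - 0.7) < 4 * sigma


class TestMergeSymmetric:
    def rec(self, pos, strand, m, t, context="CpG"):
        return CytosineRecord("chr1", pos, strand, context, m, t)

    def test_dyad_counts_pool(self):
        merged = merge_symmetric_cpgs([self.rec(5, "+", 3, 4), self.rec(6, "-", 2, 2)])
        assert len(merged) == 1
        r = merged[0]
        assert (r.pos, r.meth, r.total, r.context) == (5, 5, 6, "CpG-sym")

    def test_orphan_minus_record(self):
        merged = merge_symmetric_cpgs([self.rec(6, "-", 2, 2)])
        assert merged[0].pos == 5 and merged[0].context == "CpG-sym"

    def test_idempotent_and_conserving(self):
        records = [
            self.rec(5, "+", 3, 4), self.rec(6, "-", 2, 2),
            self.rec(10, "+", 1, 2, "CHH"), self.rec(20, "+", 0, 3),
        ]
        merged = merge_symmetric_cpgs(records)
        assert merge_symmetric_cpgs(merged) == merged
        assert sum(r.meth for r in merged) == sum(r.meth for r in records)
        assert sum(r.total for r in merged) == sum(r.total for r in records)


class TestConfidenceInterval:
    def test_wilson_frozen_and_oracle(self):
        lower, upper = level_confidence_interval(5, 5, 0.95)
        assert (round(lower, 3), round(upper, 3)) == (0.566, 1.000)
        for m, t in [(0, 10), (3, 7), (5, 5), (19, 20)]:
            lo, up = level_confidence_interval(m, t, 0.95)
            olo, oup = wilson_interval(m, t, 0.95)
            assert lo == pytest.approx(olo, abs=1e-9)
            assert up == pytest.approx(oup, abs=1e-9)

    def test_boundary_and_monotone_width(self):
        lower, _ = level_confidence_interval(0, 10)
        assert lower == pytest.approx(0.0, abs=1e-12)
        widths = [
            np.diff(level_confidence_interval(t // 2, t))[0] for t in (4, 16, 64, 256)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))
        with pytest.raises(ValueError):
            level_confidence_interval(0, 0)


class TestRegionLevels:
    def sites(self):
        return [
            CytosineRecord("chr1", 10, "+", "CpG-sym", 2, 4),
            CytosineRecord("chr1", 20, "+", "CpG-sym", 0, 2),
            CytosineRecord("chr1", 30, "+", "CpG-sym", 0, 0),
        ]

    def test_statistics(self):
        rl = region_levels(self.sites(), GenomicFeature("chr1", 0, 100))
        assert rl.mean_level == pytest.approx(0.25)
        assert rl.weighted_mean == pytest.approx(2 / 6)
        assert (rl.n_covered, rl.n_total) == (2, 3)

    def test_uncovered_region_flagged(self):
        rl = region_levels(self.sites(), GenomicFeature("chr1", 25, 35))
        assert not rl.defined

    def test_single_site_statistics_coincide(self):
        rl = region_levels(self.sites()[:1], GenomicFeature("chr1", 0, 15))
        assert rl.mean_level == rl.weighted_mean == pytest.approx(0.5)

    def test_weighted_mean_pools_across_regions(self):
        records = self.sites()
        whole = region_levels(records, GenomicFeature("chr1", 0, 100)).weighted_mean
        m = sum(r.meth for r in records)
        t = sum(r.total for r in records)
        assert whole == pytest.approx(m / t)


class TestSummary:
    def test_hand_example_and_empty(self):
        records = [
            CytosineRecord("chr1", 1, "+", "CpG-sym", 2, 4),
            CytosineRecord("chr1", 5, "+", "CpG-sym", 0, 0),
        ]
        s = methylome_summary(records)
        assert s.mean_coverage == pytest.approx(2.0)
        assert s.n_covered_cpg == 1 and s.n_covered_cytosines == 1
        empty = methylome_summary([])
        assert empty.n_sites == 0 and empty.mean_coverage == 0.0

    def test_summary_matches_simulation_coverage(self, hmr_sim):
        config, records, _ = hmr_sim
        s = methylome_summary(records)
        sigma = np.sqrt(config.coverage / len(records))
        assert abs(s.mean_coverage - config.coverage) < 3 * sigma


class TestCoverageDensityQC:
    def test_density_independent_coverage_uncorrelated(self):
        """Coverage drawn independently of density gives r near 0."""
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.integers(2, 60, size=30_000))
        records = [
            CytosineRecord("chr1", int(p), "+", "CpG-sym", 0, int(rng.poisson(10)))
            for p in pos
        ]
        r, _, n_bins = coverage_density_correlation(records)
        assert n_bins >= 900
        assert abs(r) < 0.05

    def test_density_proportional_coverage(self):
        rng = np.random.default_rng(1)
        pos = np.cumsum(rng.integers(2, 60, size=3000))
        density = np.bincount(pos // 1000)
        records = [
            CytosineRecord("chr1", int(p), "+", "CpG-sym", 0, int(density[p // 1000]))
            for p in pos
        ]
        r, _, _ = coverage_density_correlation(records)
        assert r > 0.99
        anti = [
            CytosineRecord(
                "chr1", int(p), "+", "CpG-sym", 0, int(density.max() - density[p // 1000])
            )
            for p in pos
        ]
        r2, _, _ = coverage_density_correlation(anti)
        assert r2 < -0.99

    def test_too_few_bins_rejected(self):
        records = [CytosineRecord("chr1", 10, "+", "CpG-sym", 0, 5)]
        with pytest.raises(ValueError, match="bins"):
            coverage_density_correlation(records)
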