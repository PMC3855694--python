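"""Duplicate removal, mate-overlap clipping and conversion-rate estimation."""

import numpy as np
import pytest
from scipy import stats

from methkit import (
    MappedRead,
    clip_mate_overlap,
    estimate_bsrate,
    remove_duplicates,
    simulate_bs_reads,
)


def mk(start, end, strand="+", name="r", library="libA", qual=40):
    n = end - start
    return MappedRead("chr1", start, end, strand, name, "A" * n, [qual] * n, library)


class TestRemoveDuplicates:
    def test_collapses_identical_keys(self):
        reads = [mk(0, 10, name=f"d{i}") for i in range(3)] + [mk(20, 30), mk(40, 50)]
        kept = remove_duplicates(reads, seed=0)
        assert len(kept) == 3

    def test_libraries_never_collapse(self):
        reads = [mk(0, 10, library="libA"), mk(0, 10, library="libB")]
        assert len(remove_duplicates(reads, seed=0)) == 2

    def test_selection_is_uniform(self):
        """Each of 3 duplicates is chosen ~1/3 of the time (chi-square)."""
        reads = [mk(0, 10, name=f"d{i}") for i in range(3)]
        counts = np.zeros(3)
        for trial in range(10_000):
            kept = remove_duplicates(reads, seed=trial)
            counts[int(kept[0].name[1])] += 1
        _, p = stats.chisquare(counts)
        assert p > 1e-3

    def test_idempotent_and_size_bounds(self):
        rng = np.random.default_rng(2)
        reads = sorted(
            (mk(int(s), int(s) + 10, name=f"r{i}") for i, s in
             enumerate(rng.integers(0, 50, size=40))),
            key=lambda r: (r.chrom, r.start, r.end, r.strand),
        )
        once = remove_duplicates(reads, seed=1)
        assert len(once) <= len(reads)
        assert remove_duplicates(once, seed=2) == once
        distinct = [mk(i * 20, i * 20 + 10) for i in range(5)]
        assert len(remove_duplicates(distinct, seed=0)) == 5

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="unsorted"):
            remove_duplicates([mk(20, 30), mk(0, 10)], seed=0)


class TestClipMateOverlap:
    def test_lower_quality_mate_clipped(self):
        m1 = mk(100, 150, qual=40)  # overlap qualsum 10*40 = 400
        m2 = mk(140, 190, qual=30)  # overlap qualsum 10*30 = 300
        c1, c2 = clip_mate_overlap(m1, m2)
        assert (c1.start, c1.end) == (100, 150)
        assert (c2.start, c2.end) == (150, 190)
        assert len(c2.bases) == 40

    def test_disjoint_unchanged(self):
        m1, m2 = mk(0, 50), mk(60, 110)
        assert clip_mate_overlap(m1, m2) == (m1, m2)

    def test_contained_lower_quality_mate_dropped(self):
        m1 = mk(100, 200, qual=40)
        m2 = mk(120, 160, qual=10)
        c1, c2 = clip_mate_overlap(m1, m2)
        assert c2 is None and c1 == m1

    def test_no_position_covered_twice(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            s1, s2 = rng.integers(0, 60, size=2)
            l1, l2 = rng.integers(10, 60, size=2)
            m1 = mk(int(s1), int(s1 + l1), qual=int(rng.integers(10, 41)))
            m2 = mk(int(s2), int(s2 + l2), qual=int(rng.integers(10, 41)))
            c1, c2 = clip_mate_overlap(m1, m2)
            cover = np.zeros(200, dtype=int)
            for c in (c1, c2):
                if c is not None:
                    cover[c.start : c.end] += 1
            assert cover.max() <= 1

    def test_different_chromosomes_rejected(self):
        m2 = MappedRead("chr2", 0, 10, "+", "r", "A" * 10, [40] * 10, "libA")
        with pytest.raises(ValueError, match="chromosome"):
            clip_mate_overlap(mk(0, 10), m2)


class TestBsRate:
    def test_hand_counts(self):
        controls = [("chr1", i, "+") for i in range(100)]
        reads = [
            MappedRead("chr1", 0, 100, "+", "r", "T" * 98 + "C" * 2, [40] * 100, "l")
        ]
        res = estimate_bsrate(reads, controls)
        assert res.rate == pytest.approx(0.98)
        assert (res.n_converted, res.n_total) == (98, 100)

    def test_no_observations_undefined(self):
        res = estimate_bsrate([], [("chr1", 5, "+")])
        assert res.rate is None and res.n_total == 0

    def test_simulated_conversion_rate(self):
        """1% conversion failure on unmethylated DNA -> rate ~ 0.99."""
        reference = ("ACGT" * 300)
        reads = simulate_bs_reads(
            reference, n_reads=400, read_len=60, levels=0.0,
            conversion_rate=0.99, seed=11,
        )
        controls = [
            ("chr1", i, "+" if b == "C" else "-")
            for i, b in enumerate(reference)
            if b in "CG"
        ]
        res = estimate_bsrate(reads, controls)
        sigma = np.sqrt(0.99 * 0.01 / res.n_total)
        assert abs(res.rate - 0.99) < 3 * sigma
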