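"""Differential scores, HMR fragment algebra, and both DMR callers."""

import numpy as np
import pytest
from scipy import stats

from methkit import (
    BetaBinomialParams,
    GenomicFeature,
    SimConfig,
    baum_welch,
    call_dmrs_fragment,
    call_dmrs_hmm,
    call_hmrs,
    diff_score,
    diff_scores,
    hmr_fragments,
    interval_jaccard,
)
from methkit.dmr import ScoredSite
from methkit.simulate import simulate_methylome_pair
from ._oracles import integrate_diff_score


class TestDiffScore:
    def test_small_count_example(self):
        assert diff_score(2, 2, 0, 2) == pytest.approx(5 / 6, abs=1e-12)

    def test_tied_unmethylated_sites(self):
        s = diff_score(0, 5, 0, 5)
        s_swapped = diff_score(0, 5, 0, 5)
        assert s < 0.5 and s == s_swapped

    def test_uncovered_undefined(self):
        assert diff_score(0, 0, 1, 2) is None
        assert diff_score(1, 2, 0, 0) is None

    def test_large_counts_approach_one(self):
        assert diff_score(180, 200, 20, 200) > 0.999999

    def test_matches_integration_oracle_small_grid(self):
        for t_a in range(1, 7):
            for t_b in range(1, 7):
                for m_a in range(t_a + 1):
                    for m_b in range(t_b + 1):
                        ours = diff_score(m_a, t_a, m_b, t_b)
                        oracle = integrate_diff_score(m_a, t_a, m_b, t_b)
                        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_fisher_equivalence_spot_checks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t_a, t_b = rng.integers(1, 15, size=2)
            m_a = int(rng.integers(0, t_a + 1))
            m_b = int(rng.integers(0, t_b + 1))
            table = [[m_a, t_a - m_a], [m_b, t_b - m_b]]
            _, p = stats.fisher_exact(table, alternative="greater")
            assert 1 - diff_score(m_a, int(t_a), m_b, int(t_b)) == pytest.approx(
                p, abs=1e-12
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            diff_score(3, 2, 0, 2)


class TestHmrFragments:
    def test_interval_algebra_examples(self):
        A = [GenomicFeature("chr1", 100, 200)]
        B = [GenomicFeature("chr1", 150, 250)]
        frags = hmr_fragments(A, B)
        assert [(f.start, f.end, f.name) for f in frags] == [
            (100, 150, "A"), (200, 250, "B")
        ]
        assert hmr_fragments(A, A) == []
        only_a = hmr_fragments(A, [])
        assert [(f.start, f.end, f.name) for f in only_a] == [(100, 200, "A")]

    def test_brute_force_membership(self):
        """Fragment union equals the per-base symmetric difference."""
        rng = np.random.default_rng(1)
        for trial in range(20):
            def random_set():
                feats = []
                cursor = 0
                for _ in range(rng.integers(1, 6)):
                    cursor += int(rng.integers(1, 20))
                    end = cursor + int(rng.integers(1, 20))
                    feats.append(GenomicFeature("chr1", cursor, end))
                    cursor = end
                return feats

            A, B = random_set(), random_set()
            frags = hmr_fragments(A, B)
            size = 300
            in_a = np.zeros(size, bool)
            in_b = np.zeros(size, bool)
            for f in A:
                in_a[f.start : f.end] = True
            for f in B:
                in_b[f.start : f.end] = True
            in_frag = np.zeros(size, bool)
            origin = np.full(size, " ")
            for f in frags:
                assert not in_frag[f.start : f.end].any()  # disjoint
                in_frag[f.start : f.end] = True
                origin[f.start : f.end] = f.name
            assert np.array_equal(in_frag, in_a ^ in_b)
            assert np.all((origin == "A") == (in_a & ~in_b))


class TestFragmentCaller:
    def scored(self, positions, score, score_rev):
        return [ScoredSite("chr1", int(p), score, score_rev) for p in positions]

    def test_lack_of_data_fragment_dropped(self):
        frag = [GenomicFeature("chr1", 0, 100, name="A")]
        scores = self.scored(range(0, 50, 10), 0.0, 0.999)  # only 5 < min_covered
        assert call_dmrs_fragment(frag, scores, min_covered=10) == []

    def test_min_sig_larger_than_fragment(self):
        frag = [GenomicFeature("chr1", 0, 100, name="A")]
        scores = self.scored(range(0, 100, 10), 0.0, 0.999)
        assert call_dmrs_fragment(frag, scores, min_sig_cpgs=20) == []
        called = call_dmrs_fragment(frag, scores, min_sig_cpgs=5)
        assert len(called) == 1 and called[0].name == "DMR_A_hypo"
        assert called[0].score == 10

    def test_direction_matching(self):
        frag_b = [GenomicFeature("chr1", 0, 100, name="B")]
        sig_for_a = self.scored(range(0, 100, 10), 0.0, 0.999)
        assert call_dmrs_fragment(frag_b, sig_for_a) == []  # wrong direction
        sig_for_b = self.scored(range(0, 100, 10), 0.999, 0.0)
        assert len(call_dmrs_fragment(frag_b, sig_for_b)) == 1


class TestHmmCaller:
    def test_requires_enough_sites(self):
        scores = [ScoredSite("chr1", i, 0.5, 0.4) for i in range(50)]
        with pytest.raises(ValueError, match="100"):
            call_dmrs_hmm(scores)

    def test_split_half_null_is_quiet(self):
        hits = 0
        for seed in (100, 101, 102):
            a, b, _ = simulate_methylome_pair(
                SimConfig(n_cpgs=3000, mean_gap_cpgs=1e12), seed=seed
            )
            hits += bool(call_dmrs_hmm(diff_scores(a, b)))
        assert hits == 0

    def test_sample_swap_flips_direction(self):
        cfg = SimConfig(
            n_cpgs=2000, background=BetaBinomialParams(16, 4),
            feature=BetaBinomialParams(50, 50), mean_feature_cpgs=150,
            mean_gap_cpgs=800, feature_name="DMR",
        )
        a, b, truth = simulate_methylome_pair(
            cfg, emissions_a={1: BetaBinomialParams(16, 4)}, seed=9
        )
        fwd = call_dmrs_hmm(diff_scores(a, b))
        rev = call_dmrs_hmm(diff_scores(b, a))
        assert [(f.start, f.end) for f in fwd] == [(f.start, f.end) for f in rev]
        flip = {"DMR_A_over_B": "DMR_B_over_A", "DMR_B_over_A": "DMR_A_over_B"}
        assert [flip[f.name] for f in fwd] == [f.name for f in rev]
        assert interval_jaccard(fwd, truth.features["DMR"]) >= 0.8


def test_division_of_labor_partial_difference():
    """A partial (0.8 vs 0.5) block: found by the HMM method, invisible to
    the HMR-fragment method under shared segmentation parameters."""
    cfg = SimConfig(n_cpgs=4000, background=BetaBinomialParams(16, 4))
    a, b, truth = simulate_methylome_pair(
        cfg, diff_windows=[(1900, 2100)],
        diff_a=BetaBinomialParams(16, 4), diff_b=BetaBinomialParams(50, 50),
        seed=13,
    )
    params, _ = baum_welch(a)
    hmrs_a = call_hmrs(a, params)
    hmrs_b = call_hmrs(b, params)
    scores = diff_scores(a, b)
    block = truth.features["DIFF"][0]

    fragment_calls = call_dmrs_fragment(hmr_fragments(hmrs_a, hmrs_b), scores)
    assert not any(
        f.start < block.end and f.end > block.start for f in fragment_calls
    )
    hmm_calls = call_dmrs_hmm(scores)
    assert interval_jaccard(hmm_calls, [block]) >= 0.8
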