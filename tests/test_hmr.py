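"""Beta-binomial emission model, Baum-Welch training and HMR calling."""


import numpy as np
import pytest
from scipy import stats

from methkit import (
    BetaBinomialParams,
    CytosineRecord,
    HmmParams,
    baum_welch,
    betabinom_log_pmf,
    call_hmrs,
    fit_betabinom,
    hmr_stats,
    simulate_methylome,
    state_posteriors,
    SimConfig,
)
from methkit.hmr import forward_backward
from ._oracles import enum_hmm_posteriors


def make_records(levels, t=20, spacing=50):
    return [
        CytosineRecord("chr1", (i + 1) * spacing, "+", "CpG-sym",
                       int(round(lv * t)), t)
        for i, lv in enumerate(levels)
    ]


class TestBetaBinomPmf:
    def test_uniform_prior_examples(self):
        p = BetaBinomialParams(1.0, 1.0)
        assert betabinom_log_pmf(1, 1, p) == pytest.approx(np.log(0.5))
        assert betabinom_log_pmf(2, 2, p) == pytest.approx(np.log(1 / 3))

    def test_missing_observation_is_neutral(self):
        assert betabinom_log_pmf(0, 0, BetaBinomialParams(3, 7)) == 0.0

    def test_binomial_limit(self):
        """Huge concentration at mean 1/2 converges to Binomial(t, 0.5).

        The residual pmf difference is the genuine beta-binomial
        overdispersion ~ (t-1)/(2 alpha), so it shrinks as 1/alpha: about
        1.4e-6 at alpha = 1e6 and t = 50, ten-fold smaller at 1e7.
        """
        for alpha, bound in ((1e6, 2e-6), (1e7, 2e-7)):
            p = BetaBinomialParams(alpha, alpha)
            worst = 0.0
            for t in (1, 5, 20, 50):
                m = np.arange(t + 1)
                ours = np.exp(betabinom_log_pmf(m, t, p))
                ref = stats.binom.pmf(m, t, 0.5)
                worst = max(worst, np.abs(ours - ref).max())
            assert worst < bound

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            betabinom_log_pmf(3, 2, BetaBinomialParams(1, 1))
        with pytest.raises(ValueError):
            BetaBinomialParams(0.0, 1.0)


class TestFitBetaBinom:
    def test_recovery_from_simulation(self):
        rng = np.random.default_rng(0)
        t = rng.poisson(20, size=10_000)
        p = rng.beta(2.0, 18.0, size=10_000)
        m = rng.binomial(t, p)
        fitted = fit_betabinom(m, t)
        assert fitted.mean == pytest.approx(0.1, rel=0.05)

    def test_symmetric_data_gives_half(self):
        m = np.array([0, 2] * 50)
        t = np.full(100, 2)
        assert fit_betabinom(m, t).mean == pytest.approx(0.5, abs=1e-3)

    def test_weighted_fit_follows_weights(self):
        m = np.array([0, 18])
        t = np.array([20, 20])
        w = np.array([1.0, 1e-6])
        assert fit_betabinom(m, t, w).mean < 0.05

    def test_degenerate_input_warns_with_floor(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fitted = fit_betabinom(np.full(10, 2), np.full(10, 4))
        assert fitted.mean == pytest.approx(0.5, abs=1e-3)


class TestForwardBackward:
    def test_posteriors_match_enumeration(self):
        """Scaled forward-backward equals brute-force path summation."""
        rng = np.random.default_rng(1)
        logB = np.log(rng.random((10, 2)))
        trans = np.array([[0.9, 0.1], [0.3, 0.7]])
        init = np.array([0.6, 0.4])
        ll, gamma, _ = forward_backward(logB, trans, init)
        oll, ogamma = enum_hmm_posteriors(logB, trans, init)
        assert ll == pytest.approx(oll, abs=1e-9)
        assert np.abs(gamma - ogamma).max() < 1e-9

    def test_posteriors_normalized(self, hmr_sim):
        _, records, _ = hmr_sim
        params, _ = baum_welch(records[:2000], max_iter=5)
        gamma = state_posteriors(records[:2000], params)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-12)


class TestBaumWelch:
    def test_parameter_recovery(self):
        config = SimConfig(n_cpgs=20_000, seed=6)
        records, _ = simulate_methylome(config)
        params, trace = baum_welch(records)
        assert params.emissions[0].mean == pytest.approx(0.85, abs=0.05)
        assert params.emissions[1].mean == pytest.approx(0.05, abs=0.05)
        assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_fixed_point_stops_quickly(self, hmr_sim):
        _, records, _ = hmr_sim
        sub = records[:3000]
        params, _ = baum_welch(sub)
        again, trace = baum_welch(sub, init=params, tol=1e-4)
        assert len(trace) <= 2
        assert again.emissions[1].mean == pytest.approx(
            params.emissions[1].mean, abs=1e-3
        )

    def test_all_uncovered_rejected(self):
        records = make_records([0.0] * 50, t=0)
        with pytest.raises(ValueError, match="uncovered"):
            baum_welch(records)


class TestCallHmrs:
    def test_well_separated_block(self):
        levels = [1.0] * 200 + [0.0] * 30 + [1.0] * 200
        records = make_records(levels)
        feats = call_hmrs(records)
        assert len(feats) == 1
        f = feats[0]
        assert f.start == records[200].pos and f.end == records[229].pos + 1
        assert f.score == 30

    def test_uniform_methylated_gives_nothing(self):
        rng = np.random.default_rng(4)
        levels = rng.beta(17, 3, size=400)
        records = make_records(levels)
        params = HmmParams(
            trans=np.array([[0.99, 0.01], [0.05, 0.95]]),
            init=np.array([0.5, 0.5]),
            emissions=(BetaBinomialParams(17, 3), BetaBinomialParams(1, 19)),
        )
        assert call_hmrs(records, params) == []

    def test_output_disjoint_sorted_min_cpgs(self, hmr_sim):
        _, records, _ = hmr_sim
        feats = call_hmrs(records, min_cpgs=5)
        for a, b in zip(feats, feats[1:]):
            assert a.end <= b.start
        assert all(f.score >= 5 for f in feats)

    def test_viterbi_agrees_on_strong_signal(self):
        levels = [0.95] * 100 + [0.02] * 40 + [0.95] * 100
        records = make_records(levels)
        post = call_hmrs(records)
        vit = call_hmrs(records, use_viterbi=True)
        assert [(f.start, f.end) for f in post] == [(f.start, f.end) for f in vit]

    def test_desert_splits_runs(self):
        low = [0.0] * 30
        records = make_records(low, spacing=50)
        far = [
            CytosineRecord("chr1", 10_000 + i * 50, "+", "CpG-sym", 0, 20)
            for i in range(30)
        ]
        params = HmmParams(
            trans=np.array([[0.99, 0.01], [0.05, 0.95]]),
            init=np.array([0.5, 0.5]),
            emissions=(BetaBinomialParams(17, 3), BetaBinomialParams(1, 19)),
        )
        feats = call_hmrs(records + far, params, desert_size=1000)
        assert len(feats) == 2  # the >1 kb gap forces two features


def test_hmr_stats_examples():
    from methkit import GenomicFeature

    feats = [
        GenomicFeature("chr1", 0, 100),
        GenomicFeature("chr1", 200, 500),
        GenomicFeature("chr1", 600, 800),
    ]
    count, median = hmr_stats(feats)
    assert (count, median) == (3, 200.0)
    assert hmr_stats([]) == (0, None)
    assert hmr_stats(feats[:1]) == (1, 100.0)
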