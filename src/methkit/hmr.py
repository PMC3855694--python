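"""Hypo-methylated region (HMR) calling with a two-state beta-binomial HMM.

Mammalian methylomes are highly methylated outside of discrete intervals of
low methylation (HMRs) that mark CpG islands, promoters, enhancers and other
regulatory regions.  Rather than thresholding noisy per-site level estimates,
the caller models the observed read counts directly: at site *i* with ``t_i``
reads of which ``m_i`` show methylation,

    m_i | state s  ~  BetaBinomial(t_i, alpha_s, beta_s),

with one state for the methylated background and one for hypo-methylated
intervals.  The beta-binomial absorbs both the binomial sampling noise of
finite coverage and the biological overdispersion of methylation levels.
Uncovered sites (t == 0) are traversed by the chain but contribute emission
likelihood 1.  Parameters are trained by Baum-Welch (EM); segments of the
genome separated by coverage deserts longer than ``desert_size`` are treated
as independent chains.  HMRs are the maximal runs of sites whose posterior
probability of the hypo state exceeds 0.5 (ties go to background), with a
minimum-CpG filter.

The scaled forward-backward and Viterbi primitives here are reused by the
PMD and differential-methylation modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.special import betaln, gammaln

from .io import CytosineRecord, GenomicFeature, check_sorted_records

__all__ = [
    "BetaBinomialParams",
    "HmmParams",
    "betabinom_log_pmf",
    "fit_betabinom",
    "baum_welch",
    "state_posteriors",
    "call_hmrs",
    "hmr_stats",
    "records_to_arrays",
    "split_chains",
    "forward_backward",
    "viterbi",
]


# ---------------------------------------------------------------------------
# beta-binomial emission distribution


@dataclass
class BetaBinomialParams:
    """Shape parameters of a beta-binomial emission distribution."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.alpha)
            and np.isfinite(self.beta)
            and self.alpha > 0
            and self.beta > 0
        ):
            raise ValueError(
                f"beta-binomial shapes must be positive and finite, got "
                f"alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def betabinom_log_pmf(m, t, params: BetaBinomialParams):
    """Log pmf of BetaBinomial(t, alpha, beta) at m, elementwise.

    Sites with t == 0 are missing observations and contribute log 1 = 0.
    """
    m = np.asarray(m)
    t = np.asarray(t)
    if np.any(m > t) or np.any(m < 0):
        raise ValueError("require 0 <= m <= t")
    a, b = params.alpha, params.beta
    with np.errstate(invalid="ignore"):
        out = (
            gammaln(t + 1)
            - gammaln(m + 1)
            - gammaln(t - m + 1)
            + betaln(m + a, t - m + b)
            - betaln(a, b)
        )
    return np.where(t > 0, out, 0.0)


def _weighted_bb_loglik(a: float, b: float, m, t, w) -> float:
    return float(
        np.sum(
            w
            * (
                gammaln(t + 1)
                - gammaln(m + 1)
                - gammaln(t - m + 1)
                + betaln(m + a, t - m + b)
                - betaln(a, b)
            )
        )
    )


_DISPERSION_FLOOR = 1e4  # alpha+beta used when the data carry no dispersion signal
_MIN_SHAPE = 1e-3
_MAX_SHAPE = 1e6  # beyond this, betaln cancellation loses the pmf entirely


def fit_betabinom(m, t, weights=None) -> BetaBinomialParams:
    """Weighted maximum-likelihood beta-binomial fit.

    Starts from a method-of-moments estimate and refines it numerically; the
    returned parameters never have lower weighted log-likelihood than the
    moment start.  Degenerate input (all observed levels identical) falls
    back to mean-matched shapes with the dispersion floor and warns.
    """
    m = np.asarray(m, dtype=float)
    t = np.asarray(t, dtype=float)
    w = np.ones_like(m) if weights is None else np.asarray(weights, dtype=float)
    keep = (t > 0) & (w > 0)
    m, t, w = m[keep], t[keep], w[keep]
    if w.sum() <= 0 or m.size == 0:
        raise ValueError("fit_betabinom requires positive total weight on covered sites")

    levels = m / t
    mu = float(np.sum(w * m) / np.sum(w * t))
    mu = min(max(mu, 1e-6), 1 - 1e-6)
    var = float(np.sum(w * (levels - mu) ** 2) / np.sum(w))
    if np.unique(levels).size < 2 or var <= 0:
        warnings.warn(
            "degenerate beta-binomial input (no level variation); "
            "returning mean-matched parameters with dispersion floor",
            stacklevel=2,
        )
        return BetaBinomialParams(mu * _DISPERSION_FLOOR, (1 - mu) * _DISPERSION_FLOOR)

    nu = mu * (1 - mu) / var - 1.0  # alpha + beta under a pure-beta moment match
    nu = float(np.clip(nu, 0.05, _DISPERSION_FLOOR))
    start = np.array([np.log(max(mu * nu, _MIN_SHAPE)), np.log(max((1 - mu) * nu, _MIN_SHAPE))])

    def clip(x):
        return np.clip(np.exp(x), _MIN_SHAPE, _MAX_SHAPE)

    def neg(x):
        a, b = clip(x)
        return -_weighted_bb_loglik(a, b, m, t, w)

    res = minimize(neg, start, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8})
    best = res.x if -res.fun >= -neg(start) else start
    a, b = clip(best)
    return BetaBinomialParams(a, b)


# ---------------------------------------------------------------------------
# HMM parameterization


@dataclass
class HmmParams:
    """Two-state HMM: state 0 = methylated background, state 1 = hypo."""

    trans: np.ndarray
    init: np.ndarray
    emissions: tuple[BetaBinomialParams, BetaBinomialParams]

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=float)
        self.init = np.asarray(self.init, dtype=float)
        if self.trans.shape != (2, 2) or self.init.shape != (2,):
            raise ValueError("trans must be 2x2 and init length 2")
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.init.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")
        if self.emissions[1].mean >= self.emissions[0].mean:
            raise ValueError(
                "state 1 (hypo) must have lower emission mean than state 0"
            )


# ---------------------------------------------------------------------------
# scaled forward-backward / Viterbi cores (generic in the number of states)


@njit(cache=True)
def _fb_core(B, A, pi):
    n, S = B.shape
    alpha = np.empty((n, S))
    beta = np.empty((n, S))
    c = np.empty(n)
    for s in range(S):
        alpha[0, s] = pi[s] * B[0, s]
    c[0] = alpha[0].sum()
    for s in range(S):
        alpha[0, s] /= c[0]
    for i in range(1, n):
        for s in range(S):
            acc = 0.0
            for r in range(S):
                acc += alpha[i - 1, r] * A[r, s]
            alpha[i, s] = acc * B[i, s]
        c[i] = alpha[i].sum()
        for s in range(S):
            alpha[i, s] /= c[i]
    for s in range(S):
        beta[n - 1, s] = 1.0
    for i in range(n - 2, -1, -1):
        for s in range(S):
            acc = 0.0
            for r in range(S):
                acc += A[s, r] * B[i + 1, r] * beta[i + 1, r]
            beta[i, s] = acc / c[i + 1]
    return alpha, beta, c


@njit(cache=True)
def _xi_core(alpha, beta, c, B, A):
    n, S = B.shape
    xi = np.zeros((S, S))
    for i in range(n - 1):
        for r in range(S):
            for s in range(S):
                xi[r, s] += alpha[i, r] * A[r, s] * B[i + 1, s] * beta[i + 1, s] / c[i + 1]
    return xi


@njit(cache=True)
def _viterbi_core(logB, logA, logpi):
    n, S = logB.shape
    delta = np.empty((n, S))
    back = np.zeros((n, S), dtype=np.int64)
    for s in range(S):
        delta[0, s] = logpi[s] + logB[0, s]
    for i in range(1, n):
        for s in range(S):
            best = -1e300
            arg = 0
            for r in range(S):
                v = delta[i - 1, r] + logA[r, s]
                if v > best:
                    best = v
                    arg = r
            delta[i, s] = best + logB[i, s]
            back[i, s] = arg
    path = np.empty(n, dtype=np.int64)
    path[n - 1] = np.argmax(delta[n - 1])
    for i in range(n - 2, -1, -1):
        path[i] = back[i + 1, path[i + 1]]
    return path


def forward_backward(logB: np.ndarray, trans: np.ndarray, init: np.ndarray):
    """Scaled forward-backward over one chain.

    Parameters
    ----------
    logB : (n, S) array of per-site per-state emission log-likelihoods.

    Returns
    -------
    loglik, gamma (n, S posteriors), xi_sums (S, S expected transition counts).
    """
    logB = np.asarray(logB, dtype=float)
    shift = logB.max(axis=1, keepdims=True)
    B = np.exp(logB - shift)
    alpha, beta, c = _fb_core(B, np.asarray(trans, float), np.asarray(init, float))
    loglik = float(np.sum(np.log(c)) + np.sum(shift))
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = _xi_core(alpha, beta, c, B, np.asarray(trans, float))
    return loglik, gamma, xi


def viterbi(logB: np.ndarray, trans: np.ndarray, init: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return _viterbi_core(
            np.asarray(logB, float),
            np.log(np.asarray(trans, float)),
            np.log(np.asarray(init, float)),
        )


# ---------------------------------------------------------------------------
# record <-> array plumbing


def records_to_arrays(records: Sequence[CytosineRecord]):
    """Sorted records -> (chroms, pos, m, t) numpy arrays."""
    check_sorted_records(records)
    chroms = np.array([r.chrom for r in records])
    pos = np.array([r.pos for r in records], dtype=np.int64)
    m = np.array([r.meth for r in records], dtype=np.int64)
    t = np.array([r.total for r in records], dtype=np.int64)
    return chroms, pos, m, t


def split_chains(chroms: np.ndarray, pos: np.ndarray, desert_size: int | None):
    """Index ranges of independent chains, split at chromosome breaks and,
    when ``desert_size`` is given, at inter-site gaps larger than it."""
    n = len(pos)
    if n == 0:
        return []
    breaks = [0]
    for i in range(1, n):
        if chroms[i] != chroms[i - 1] or (
            desert_size is not None and pos[i] - pos[i - 1] > desert_size
        ):
            breaks.append(i)
    breaks.append(n)
    return [(breaks[k], breaks[k + 1]) for k in range(len(breaks) - 1)]


# ---------------------------------------------------------------------------
# EM over arrays (shared with the PMD caller)


def _tercile_init(m: np.ndarray, t: np.ndarray) -> tuple[BetaBinomialParams, BetaBinomialParams]:
    """Method-of-moments emissions from the upper/lower terciles of site levels."""
    cov = t > 0
    levels = m[cov] / t[cov]
    lo, hi = np.quantile(levels, [1 / 3, 2 / 3])
    low_mask = levels <= lo
    high_mask = levels >= hi
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hypo = fit_betabinom(m[cov][low_mask], t[cov][low_mask])
        bg = fit_betabinom(m[cov][high_mask], t[cov][high_mask])
    if hypo.mean >= bg.mean:  # pathological tie; nudge apart
        hypo = BetaBinomialParams(0.5, 9.5)
        bg = BetaBinomialParams(9.5, 0.5)
    return bg, hypo


def _em_two_state(
    chroms: np.ndarray,
    pos: np.ndarray,
    m: np.ndarray,
    t: np.ndarray,
    init: HmmParams | None,
    tol: float,
    max_iter: int,
    desert_size: int | None,
):
    if not np.any(t > 0):
        raise ValueError("all sites uncovered; cannot train HMM")

    if init is not None:
        return _em_two_state_from(
            chroms, pos, m, t, init, tol, max_iter, desert_size
        )
    # two starts: data-driven terciles, and a canonical methylated/hypo
    # prior — the terciles degenerate at very low coverage (levels are
    # only 0 or 1), and the canonical start rescues those fits
    bg, hypo = _tercile_init(m, t)
    starts = [
        (bg, hypo),
        (BetaBinomialParams(8.5, 1.5), BetaBinomialParams(1.0, 9.0)),
    ]
    best = None
    for emissions in starts:
        candidate = HmmParams(
            trans=np.array([[0.99, 0.01], [0.05, 0.95]]),
            init=np.array([0.5, 0.5]),
            emissions=emissions,
        )
        fitted, trace = _em_two_state_from(
            chroms, pos, m, t, candidate, tol, max_iter, desert_size
        )
        if best is None or trace[-1] > best[1][-1]:
            best = (fitted, trace)
    return best


def _em_two_state_from(
    chroms: np.ndarray,
    pos: np.ndarray,
    m: np.ndarray,
    t: np.ndarray,
    params: HmmParams,
    tol: float,
    max_iter: int,
    desert_size: int | None,
):
    chains = split_chains(chroms, pos, desert_size)
    trace: list[float] = []
    for _ in range(max_iter):
        logB = np.column_stack(
            [betabinom_log_pmf(m, t, e) for e in params.emissions]
        )
        total_ll = 0.0
        gamma = np.empty((len(pos), 2))
        xi = np.zeros((2, 2))
        g0 = np.zeros(2)
        for a, b in chains:
            ll, g, x = forward_backward(logB[a:b], params.trans, params.init)
            total_ll += ll
            gamma[a:b] = g
            xi += x
            g0 += g[0]
        trace.append(total_ll)

        # M-step
        new_trans = xi / xi.sum(axis=1, keepdims=True)
        new_init = g0 / g0.sum()
        new_em = []
        for s, cur in enumerate(params.emissions):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = fit_betabinom(m, t, gamma[:, s])
            cov = t > 0
            w = gamma[cov, s]
            if _weighted_bb_loglik(cand.alpha, cand.beta, m[cov], t[cov], w) < _weighted_bb_loglik(
                cur.alpha, cur.beta, m[cov], t[cov], w
            ):
                cand = cur  # ascent guard
            new_em.append(cand)
        if new_em[1].mean > new_em[0].mean:  # keep hypo label on state 1
            new_em = [new_em[1], new_em[0]]
            new_trans = new_trans[::-1, ::-1]
            new_init = new_init[::-1]
        params = HmmParams(new_trans, new_init, (new_em[0], new_em[1]))

        if len(trace) >= 2:
            prev, cur_ll = trace[-2], trace[-1]
            if (cur_ll - prev) / (abs(prev) + 1e-12) < tol:
                break
    return params, trace


def _posteriors_two_state(chroms, pos, m, t, params: HmmParams, desert_size):
    logB = np.column_stack([betabinom_log_pmf(m, t, e) for e in params.emissions])
    gamma = np.empty((len(pos), 2))
    chains = split_chains(chroms, pos, desert_size)
    for a, b in chains:
        _, g, _ = forward_backward(logB[a:b], params.trans, params.init)
        gamma[a:b] = g
    return gamma, chains


# ---------------------------------------------------------------------------
# public API on records


def baum_welch(
    records: Sequence[CytosineRecord],
    init: HmmParams | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    desert_size: int | None = 1000,
) -> tuple[HmmParams, list[float]]:
    """Train the two-state beta-binomial HMM by Baum-Welch.

    ``tol`` is the relative log-likelihood improvement at which training
    stops.  The log-likelihood trace is non-decreasing up to numerical
    slack; state 1 is kept as the lower-mean (hypo) state throughout.
    """
    chroms, pos, m, t = records_to_arrays(records)
    return _em_two_state(chroms, pos, m, t, init, tol, max_iter, desert_size)


def state_posteriors(
    records: Sequence[CytosineRecord],
    params: HmmParams,
    desert_size: int | None = 1000,
) -> np.ndarray:
    """Per-site posterior state probabilities, shape (n_sites, 2)."""
    chroms, pos, m, t = records_to_arrays(records)
    gamma, _ = _posteriors_two_state(chroms, pos, m, t, params, desert_size)
    return gamma


def _runs_to_features(
    in_state: np.ndarray,
    chroms: np.ndarray,
    pos: np.ndarray,
    chains,
    min_cpgs: int,
    name_prefix: str,
) -> list[GenomicFeature]:
    features: list[GenomicFeature] = []
    for a, b in chains:
        i = a
        while i < b:
            if in_state[i]:
                j = i
                while j + 1 < b and in_state[j + 1]:
                    j += 1
                n_sites = j - i + 1
                if n_sites >= min_cpgs:
                    features.append(
                        GenomicFeature(
                            chrom=str(chroms[i]),
                            start=int(pos[i]),
                            end=int(pos[j]) + 1,
                            name=f"{name_prefix}{len(features)}",
                            score=n_sites,
                        )
                    )
                i = j + 1
            else:
                i += 1
    return features


def call_hmrs(
    records: Sequence[CytosineRecord],
    params: HmmParams | None = None,
    desert_size: int | None = 1000,
    min_cpgs: int = 5,
    use_viterbi: bool = False,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> list[GenomicFeature]:
    """Call hypo-methylated regions; trains parameters first if none given.

    A feature spans from the first to one past the last CpG of a maximal
    run of sites decoded as hypo (posterior > 0.5, ties to background, or
    Viterbi when requested); the score column holds the CpG count of the
    run.  Runs never cross chromosome breaks or coverage deserts.
    """
    chroms, pos, m, t = records_to_arrays(records)
    if params is None:
        params, _ = _em_two_state(chroms, pos, m, t, None, tol, max_iter, desert_size)
    chains = split_chains(chroms, pos, desert_size)
    if use_viterbi:
        logB = np.column_stack([betabinom_log_pmf(m, t, e) for e in params.emissions])
        in_state = np.zeros(len(pos), dtype=bool)
        for a, b in chains:
            in_state[a:b] = viterbi(logB[a:b], params.trans, params.init) == 1
    else:
        gamma, chains = _posteriors_two_state(chroms, pos, m, t, params, desert_size)
        in_state = gamma[:, 1] > 0.5
    return _runs_to_features(in_state, chroms, pos, chains, min_cpgs, "HMR")


def hmr_stats(features: Sequence[GenomicFeature]) -> tuple[int, float | None]:
    """(count, median size in bp); median is None for an empty set."""
    if not features:
        return 0, None
    sizes = np.array([f.end - f.start for f in features], dtype=float)
    return len(features), float(np.median(sizes))
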