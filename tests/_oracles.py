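"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming recursions:
posteriors are obtained by enumerating every hidden path / segmentation,
and the differential score by numerical integration of Beta densities.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from methkit.hypermr import HsmmParams, _log_survival, duration_log_pmf


def enum_hmm_posteriors(logB: np.ndarray, trans: np.ndarray, init: np.ndarray):
    """Posteriors and log-likelihood by summing over all S^n state paths."""
    n, S = logB.shape
    log_trans = np.log(trans)
    log_init = np.log(init)
    path_logps = []
    paths = list(itertools.product(range(S), repeat=n))
    for path in paths:
        lp = log_init[path[0]] + logB[0, path[0]]
        for i in range(1, n):
            lp += log_trans[path[i - 1], path[i]] + logB[i, path[i]]
        path_logps.append(lp)
    path_logps = np.array(path_logps)
    loglik = float(logsumexp(path_logps))
    gamma = np.zeros((n, S))
    for path, lp in zip(paths, path_logps):
        w = np.exp(lp - loglik)
        for i, s in enumerate(path):
            gamma[i, s] += w
    return loglik, gamma


def enum_hsmm_posteriors(logB: np.ndarray, params: HsmmParams):
    """Posteriors and log-likelihood by enumerating labeled segmentations.

    Segmentations follow the B<->H<->E topology with explicit durations;
    the final segment is right-censored (it must reach the last site and
    carries the duration survival mass P(d >= len)).
    """
    n = logB.shape[0]
    ld = np.stack([duration_log_pmf(d, params.l_max) for d in params.durations])
    lS = np.stack([_log_survival(row) for row in ld])
    with np.errstate(divide="ignore"):
        logA = np.log(params.trans_matrix)
        logpi = np.log(params.init_vector)

    terms: list[tuple[float, list[int]]] = []  # (log prob, per-site labels)

    def seg_em(state: int, start: int, dur: int) -> float:
        return float(logB[start : start + dur, state].sum())

    def rec(u: int, prev: int | None, lp: float, labels: list[int]) -> None:
        if prev is None:
            choices = [s for s in range(3) if np.isfinite(logpi[s])]
        else:
            choices = [s for s in range(3) if np.isfinite(logA[prev, s])]
        for s in choices:
            enter = logpi[s] if prev is None else logA[prev, s]
            for d in range(1, n - u + 1):
                if u + d == n:
                    dur_lp = lS[s, d - 1] if d - 1 < lS.shape[1] else -np.inf
                else:
                    dur_lp = ld[s, d - 1] if d - 1 < ld.shape[1] else -np.inf
                if not np.isfinite(dur_lp):
                    continue
                lp2 = lp + enter + dur_lp + seg_em(s, u, d)
                labels2 = labels + [s] * d
                if u + d == n:
                    terms.append((lp2, labels2))
                else:
                    rec(u + d, s, lp2, labels2)

    rec(0, None, 0.0, [])
    logps = np.array([t[0] for t in terms])
    loglik = float(logsumexp(logps))
    gamma = np.zeros((n, 3))
    for (lp, labels) in terms:
        w = np.exp(lp - loglik)
        for i, s in enumerate(labels):
            gamma[i, s] += w
    return loglik, gamma


def integrate_diff_score(m_a: int, t_a: int, m_b: int, t_b: int) -> float:
    """P(p_A > p_B) for p_A ~ Beta(m_a, u_a+1), p_B ~ Beta(m_b+1, u_b) by
    Gauss-Legendre quadrature of the density-times-CDF integrand.

    With integer shapes the integrand is a polynomial of degree < t_a + t_b
    + 2, so 128-node quadrature is exact to machine precision.  Degenerate
    zero shapes are point masses and handled directly.
    """
    u_a, u_b = t_a - m_a, t_b - m_b
    a1, b1 = m_a, u_a + 1
    a2, b2 = m_b + 1, u_b
    if a1 == 0:
        return 0.0  # p_A == 0 a.s.
    if b2 == 0:
        return 0.0  # p_B == 1 a.s.
    nodes, weights = np.polynomial.legendre.leggauss(128)
    x = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    integrand = stats.beta.pdf(x, a1, b1) * stats.beta.cdf(x, a2, b2)
    return float(np.sum(w * integrand))


def wilson_interval(m: int, t: int, conf: float) -> tuple[float, float]:
    """Closed-form Wilson score interval, written out independently."""
    z = stats.norm.ppf(0.5 + conf / 2)
    phat = m / t
    denom = 1 + z * z / t
    centre = phat + z * z / (2 * t)
    half = z * np.sqrt(phat * (1 - phat) / t + z * z / (4 * t * t))
    return (centre - half) / denom, (centre + half) / denom
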