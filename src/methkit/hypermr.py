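"""Hyper-methylated region (HyperMR) calling with an explicit-duration HMM.

Mosaic methylomes — plants such as Arabidopsis, many invertebrates, and
early mammalian germ cells — are unmethylated by default with methylation
concentrated in discrete blocks.  Three hidden states describe them:

* ``B`` — the hypo-methylated background,
* ``H`` — the HYPER-methylated state forming HyperMRs,
* ``E`` — short HYPO-methylated runs embedded inside HyperMRs.

The transition topology is ``B <-> H <-> E``: embedded runs are reachable
only from inside a HyperMR, so when decoded segments in states H and E are
merged, a short unmethylated stretch does not split a block in two.

Run lengths (in CpGs) carry an explicit duration distribution — a negative
binomial on d - 1, truncated at ``l_max`` — which generalizes the implicit
geometric duration of an ordinary HMM (recovered exactly at r = 1).
Emissions are beta-binomial on the observed counts, as in the HMR caller.
The likelihood is right-censored: the final segment of a chain is only
required to reach the last site, not to end there, which makes the
geometric-duration special case agree with the ordinary HMM to machine
precision.  Training is EM (a generalized M-step with per-component ascent
guards); decoding assigns each site to HyperMR when its posterior mass in
states H and E exceeds 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln, logsumexp

from .hmr import (
    BetaBinomialParams,
    _tercile_init,
    _weighted_bb_loglik,
    betabinom_log_pmf,
    fit_betabinom,
    records_to_arrays,
    split_chains,
    _runs_to_features,
)
from .io import CytosineRecord, GenomicFeature

__all__ = [
    "DurationParams",
    "HsmmParams",
    "duration_log_pmf",
    "hsmm_fit",
    "hsmm_posteriors",
    "call_hypermrs",
]

_B, _H, _E = 0, 1, 2
_NEG_INF = -np.inf


@dataclass
class DurationParams:
    """Negative-binomial run-length distribution: d - 1 ~ NB(r, p), d >= 1.

    r = 1 is the geometric special case (ordinary-HMM durations).
    """

    r: float
    p: float

    def __post_init__(self) -> None:
        if not (self.r > 0 and 0 < self.p < 1):
            raise ValueError(f"invalid duration params r={self.r}, p={self.p}")

    @property
    def mean(self) -> float:
        return 1.0 + self.r * (1 - self.p) / self.p


@dataclass
class HsmmParams:
    """Three-state explicit-duration HMM for mosaic methylomes."""

    emissions: tuple[BetaBinomialParams, BetaBinomialParams, BetaBinomialParams]
    durations: tuple[DurationParams, DurationParams, DurationParams]
    trans_h_to_b: float = 0.7  # H exits to B with this probability, else to E
    init_background: float = 0.5  # chains start in B with this probability, else H
    l_max: int = 500
    family: str = "nb"  # "nb" or "geometric"

    def __post_init__(self) -> None:
        if not 0 < self.trans_h_to_b < 1:
            raise ValueError("trans_h_to_b must be in (0, 1)")
        if not 0 <= self.init_background <= 1:
            raise ValueError("init_background must be in [0, 1]")
        if self.l_max < 2:
            raise ValueError("l_max must be >= 2")
        if self.family not in ("nb", "geometric"):
            raise ValueError("family must be 'nb' or 'geometric'")

    @property
    def trans_matrix(self) -> np.ndarray:
        tau = self.trans_h_to_b
        return np.array([[0.0, 1.0, 0.0], [tau, 0.0, 1 - tau], [0.0, 1.0, 0.0]])

    @property
    def init_vector(self) -> np.ndarray:
        return np.array([self.init_background, 1 - self.init_background, 0.0])


def duration_log_pmf(dur: DurationParams, l_max: int) -> np.ndarray:
    """Log pmf over run lengths 1..l_max, truncated and renormalized."""
    k = np.arange(l_max)  # d - 1
    lp = (
        gammaln(k + dur.r)
        - gammaln(dur.r)
        - gammaln(k + 1)
        + dur.r * np.log(dur.p)
        + k * np.log1p(-dur.p)
    )
    return lp - logsumexp(lp)


def _log_survival(ld_row: np.ndarray) -> np.ndarray:
    """lS[k] = log P(d >= k+1) for k = 0..L-1 (within the truncated support)."""
    rev = np.logaddexp.accumulate(ld_row[::-1])[::-1]
    return rev


# ---------------------------------------------------------------------------
# forward / backward over one chain


def _chain_pass(logB: np.ndarray, params: HsmmParams):
    """Right-censored HSMM forward-backward on one chain.

    Returns (loglik, gamma, stats) where gamma is the (n, 3) per-site state
    occupancy and stats holds the EM sufficient statistics: expected
    duration counts ``w_dur`` (3, L), expected H->B / H->E transition
    counts, and the posterior initial-state distribution.
    """
    n = logB.shape[0]
    L = min(params.l_max, n)
    ld = np.stack([duration_log_pmf(d, params.l_max) for d in params.durations])
    lS = np.full((3, max(n, params.l_max) + 1), _NEG_INF)
    lS[:, : params.l_max] = np.stack([_log_survival(row) for row in ld])
    # lS[s, k-1] = log P(d >= k); zero beyond the truncation bound
    with np.errstate(divide="ignore"):
        logA = np.log(params.trans_matrix)
        logpi = np.log(params.init_vector)

    ce = np.concatenate(
        [np.zeros((3, 1)), np.cumsum(logB.T, axis=1)], axis=1
    )  # ce[s, u] = sum of logB over sites 1..u

    # forward
    alpha = np.full((n + 1, 3), _NEG_INF)
    astar = np.full((n + 1, 3), _NEG_INF)
    astar[0] = logpi
    for u in range(1, n + 1):
        D = min(L, u)
        prev = astar[u - D : u][::-1].T  # (3, D): astar[u-d] at column d-1
        seg_em = ce[:, [u]] - ce[:, u - D : u][:, ::-1]  # (3, D)
        alpha[u] = logsumexp(prev + ld[:, :D] + seg_em, axis=1)
        if u < n:
            astar[u] = logsumexp(alpha[u][:, None] + logA, axis=0)

    # censored likelihood: the last segment reaches site n (may continue)
    us = np.arange(n)
    surv_k = n - us  # segment covers sites u+1..n -> d >= n-u
    cens = astar[:n] + lS[:, surv_k - 1].T + (ce[:, n][None, :] - ce[:, :n].T)
    loglik = float(logsumexp(cens))

    # backward
    bstar = np.full((n, 3), _NEG_INF)
    beta = np.full((n + 1, 3), _NEG_INF)
    for u in range(n - 1, -1, -1):
        Dc = min(L, n - 1 - u)
        pieces = [lS[:, n - u - 1] + ce[:, n] - ce[:, u]]  # censored final segment
        if Dc > 0:
            ends = np.arange(u + 1, u + Dc + 1)
            seg_em = ce[:, ends] - ce[:, [u]]
            pieces.append(
                logsumexp(ld[:, :Dc] + seg_em + beta[ends].T, axis=1)
            )
        bstar[u] = logsumexp(np.stack(pieces, axis=1), axis=1) if len(pieces) > 1 else pieces[0]
        if u >= 1:
            beta[u] = logsumexp(logA + bstar[u][None, :], axis=1)

    check = float(logsumexp(logpi + bstar[0]))
    if not np.isclose(check, loglik, atol=1e-6):  # pragma: no cover
        warnings.warn(f"HSMM forward/backward mismatch: {loglik} vs {check}")

    # occupancy via start/end events
    ev_start = np.exp(astar[:n] + bstar - loglik)  # segment starts at u+1
    ev_end = np.zeros((n + 1, 3))
    idx = np.arange(1, n)
    if n > 1:
        ev_end[idx] = np.exp(alpha[idx] + beta[idx] - loglik)
    gamma = np.empty((n, 3))
    running = np.zeros(3)
    for i in range(n):
        running = running + ev_start[i] - (ev_end[i] if i > 0 else 0.0)
        gamma[i] = running
    gamma = np.clip(gamma, 0.0, None)
    gamma /= gamma.sum(axis=1, keepdims=True)

    # duration expected counts (complete segments only)
    w_dur = np.zeros((3, params.l_max))
    for u in range(n - 1):
        Dc = min(L, n - 1 - u)
        if Dc <= 0:
            continue
        ends = np.arange(u + 1, u + Dc + 1)
        seg_em = ce[:, ends] - ce[:, [u]]
        contrib = np.exp(astar[u][:, None] + ld[:, :Dc] + seg_em + beta[ends].T - loglik)
        w_dur[:, :Dc] += contrib

    # H -> B vs H -> E expected transition counts
    n_hb = n_he = 0.0
    if n > 1:
        hb = np.exp(alpha[idx, _H] + logA[_H, _B] + bstar[idx, _B] - loglik)
        he = np.exp(alpha[idx, _H] + logA[_H, _E] + bstar[idx, _E] - loglik)
        n_hb = float(hb.sum())
        n_he = float(he.sum())

    pi_post = np.exp(logpi + bstar[0] - loglik)
    stats = {"w_dur": w_dur, "n_hb": n_hb, "n_he": n_he, "pi": pi_post}
    return loglik, gamma, stats


def _fit_duration(
    w: np.ndarray, current: DurationParams, l_max: int, family: str
) -> DurationParams:
    """Weighted ML fit of the truncated duration pmf; never decreases the
    expected-duration objective relative to the current parameters."""
    total = w.sum()
    if total <= 0:
        return current
    d = np.arange(1, l_max + 1)
    mean_d = float((w * d).sum() / total)

    def obj(dur: DurationParams) -> float:
        return float((w * duration_log_pmf(dur, l_max)).sum())

    if family == "geometric":
        def neg_p(logit_p):
            p = 1 / (1 + np.exp(-logit_p))
            return -obj(DurationParams(1.0, min(max(p, 1e-8), 1 - 1e-8)))

        p0 = min(max(1.0 / mean_d, 1e-6), 1 - 1e-6)
        res = minimize_scalar(neg_p, bracket=(np.log(p0 / (1 - p0)) - 1, np.log(p0 / (1 - p0)) + 1))
        p = 1 / (1 + np.exp(-res.x))
        cand = DurationParams(1.0, min(max(p, 1e-8), 1 - 1e-8))
    else:
        var_d = float((w * (d - mean_d) ** 2).sum() / total)
        mu = max(mean_d - 1.0, 1e-3)  # moments of d - 1
        r0 = mu * mu / max(var_d - mu, 1e-3) if var_d > mu else 5.0
        r0 = min(max(r0, 0.05), 1e3)
        p0 = min(max(r0 / (r0 + mu), 1e-6), 1 - 1e-6)
        x0 = np.array([np.log(r0), np.log(p0 / (1 - p0))])

        def neg(x):
            r = np.exp(x[0])
            p = 1 / (1 + np.exp(-x[1]))
            return -obj(DurationParams(min(max(r, 1e-3), 1e4), min(max(p, 1e-8), 1 - 1e-8)))

        res = minimize(neg, x0, method="Nelder-Mead", options={"xatol": 1e-5, "fatol": 1e-7})
        r = min(max(np.exp(res.x[0]), 1e-3), 1e4)
        p = min(max(1 / (1 + np.exp(-res.x[1])), 1e-8), 1 - 1e-8)
        cand = DurationParams(r, p)
    return cand if obj(cand) >= obj(current) else current


def _default_init(m: np.ndarray, t: np.ndarray, l_max: int, family: str) -> HsmmParams:
    lo, hi = _tercile_init(m, t)  # (higher-mean, lower-mean)
    high, low = lo, hi  # _tercile_init returns (bg=high tercile, hypo=low tercile)
    return HsmmParams(
        emissions=(low, high, BetaBinomialParams(low.alpha, low.beta)),
        durations=(
            DurationParams(2.0, 0.1),
            DurationParams(2.0, 0.1),
            DurationParams(2.0, 0.4),
        ),
        trans_h_to_b=0.7,
        init_background=0.5,
        l_max=l_max,
        family=family,
    )


def hsmm_fit(
    records: Sequence[CytosineRecord],
    init: HsmmParams | None = None,
    tol: float = 1e-4,
    max_iter: int = 30,
    desert_size: int | None = 1000,
    l_max: int = 500,
    family: str = "nb",
) -> tuple[HsmmParams, list[float]]:
    """Train the three-state explicit-duration HMM by (generalized) EM.

    The log-likelihood trace is non-decreasing: every M-step component is
    guarded against the current parameters.  The H state keeps the highest
    emission mean; training data with no methylated fraction will fail the
    identifiability check.
    """
    chroms, pos, m, t = records_to_arrays(records)
    if not np.any(t > 0):
        raise ValueError("all sites uncovered; cannot train HSMM")
    chains = split_chains(chroms, pos, desert_size)
    params = init if init is not None else _default_init(m, t, l_max, family)

    trace: list[float] = []
    for _ in range(max_iter):
        logB = np.column_stack([betabinom_log_pmf(m, t, e) for e in params.emissions])
        total_ll = 0.0
        gamma = np.empty((len(pos), 3))
        w_dur = np.zeros((3, params.l_max))
        n_hb = n_he = 0.0
        pi_acc = np.zeros(3)
        for a, b in chains:
            ll, g, stats = _chain_pass(logB[a:b], params)
            total_ll += ll
            gamma[a:b] = g
            w_dur += stats["w_dur"]
            n_hb += stats["n_hb"]
            n_he += stats["n_he"]
            pi_acc += stats["pi"]
        trace.append(total_ll)

        cov = t > 0
        new_em = []
        for s, cur in enumerate(params.emissions):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cand = fit_betabinom(m, t, gamma[:, s])
                except ValueError:
                    cand = cur
            w = gamma[cov, s]
            if _weighted_bb_loglik(cand.alpha, cand.beta, m[cov], t[cov], w) < _weighted_bb_loglik(
                cur.alpha, cur.beta, m[cov], t[cov], w
            ):
                cand = cur
            new_em.append(cand)

        new_dur = tuple(
            _fit_duration(w_dur[s], params.durations[s], params.l_max, params.family)
            for s in range(3)
        )
        tau = params.trans_h_to_b
        if n_hb + n_he > 0:
            tau = min(max(n_hb / (n_hb + n_he), 1e-6), 1 - 1e-6)
        pi_b = params.init_background
        if pi_acc[:2].sum() > 0:
            pi_b = float(pi_acc[_B] / pi_acc[:2].sum())

        params = HsmmParams(
            emissions=(new_em[0], new_em[1], new_em[2]),
            durations=new_dur,
            trans_h_to_b=tau,
            init_background=pi_b,
            l_max=params.l_max,
            family=params.family,
        )
        if len(trace) >= 2 and (trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-12) < tol:
            break

    if params.emissions[_H].mean <= max(
        params.emissions[_B].mean, params.emissions[_E].mean
    ):
        warnings.warn(
            "HyperMR state did not converge to the highest emission mean; "
            "the data may lack hyper-methylated blocks"
        )
    return params, trace


def hsmm_posteriors(
    records: Sequence[CytosineRecord],
    params: HsmmParams,
    desert_size: int | None = 1000,
) -> tuple[np.ndarray, float]:
    """Per-site state occupancy posteriors (n, 3) and total log-likelihood."""
    chroms, pos, m, t = records_to_arrays(records)
    chains = split_chains(chroms, pos, desert_size)
    logB = np.column_stack([betabinom_log_pmf(m, t, e) for e in params.emissions])
    gamma = np.empty((len(pos), 3))
    total_ll = 0.0
    for a, b in chains:
        ll, g, _ = _chain_pass(logB[a:b], params)
        total_ll += ll
        gamma[a:b] = g
    return gamma, total_ll


def call_hypermrs(
    records: Sequence[CytosineRecord],
    params: HsmmParams | None = None,
    min_cpgs: int = 5,
    desert_size: int | None = 1000,
    tol: float = 1e-4,
    max_iter: int = 30,
    l_max: int = 500,
    family: str = "nb",
) -> list[GenomicFeature]:
    """Call HyperMRs; trains parameters first if none are given.

    Sites with posterior mass P(H) + P(E) > 0.5 belong to a HyperMR, so
    embedded hypo-methylated runs do not split a block.  Score = CpG count.
    """
    if params is None:
        params, _ = hsmm_fit(
            records,
            tol=tol,
            max_iter=max_iter,
            desert_size=desert_size,
            l_max=l_max,
            family=family,
        )
    chroms, pos, _, _ = records_to_arrays(records)
    chains = split_chains(chroms, pos, desert_size)
    gamma, _ = hsmm_posteriors(records, params, desert_size)
    in_state = gamma[:, _H] + gamma[:, _E] > 0.5
    return _runs_to_features(in_state, chroms, pos, chains, min_cpgs, "HyperMR")
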