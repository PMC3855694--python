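"""Allele-specific methylation from read-level CpG linkage.

Bisulfite reads covering several CpGs preserve the linkage of methylation
states along one DNA molecule, so allele-specific methylation is detectable
without genotypes: in an AMR, reads fall into two populations with opposite
methylation profiles.

Two complementary tools:

* :func:`allelic_score` / :func:`allelicmeth_profile` — a per-site track:
  for each pair of adjacent CpGs, the joint methylation states of spanning
  reads form a 2x2 table (MM, MU, UM, UU) and a two-sided Fisher exact test
  scores the association ("linkage") between the two sites.

* :func:`fit_amr_window` / :func:`call_amrs` — an interval caller: in a
  sliding window of ``window_cpgs`` consecutive CpGs, a one-allele model
  (independent smoothed per-CpG levels) is compared with a two-allele
  model: an equal-weight mixture of two per-CpG level profiles into which
  reads are softly partitioned by EM (several seeded restarts; smoothed
  level updates).  The degenerate configuration with both profiles equal
  reproduces the one-allele likelihood exactly, so the two-allele
  log-likelihood never falls below the one-allele one.  Window scores are
  converted to p-values by a likelihood-ratio chi-square approximation
  (df = window size), corrected by Benjamini-Hochberg FDR, and overlapping
  significant windows are merged into AMR features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import betaln
from statsmodels.stats.multitest import multipletests

from .io import Epiread, GenomicFeature

__all__ = [
    "PairTable",
    "AmrWindowResult",
    "allelic_score",
    "allelicmeth_profile",
    "fit_amr_window",
    "call_amrs",
]


@dataclass
class PairTable:
    """Joint methylation-state counts of reads spanning two adjacent CpGs."""

    mm: int
    mu: int
    um: int
    uu: int

    def __post_init__(self) -> None:
        if min(self.mm, self.mu, self.um, self.uu) < 0:
            raise ValueError("pair-table counts must be non-negative")

    @property
    def total(self) -> int:
        return self.mm + self.mu + self.um + self.uu


def allelic_score(table: PairTable) -> float | None:
    """Two-sided Fisher exact p-value for linkage in a pair table.

    Returns None (undefined) for an empty table.
    """
    if table.total == 0:
        return None
    _, p = stats.fisher_exact(
        [[table.mm, table.mu], [table.um, table.uu]], alternative="two-sided"
    )
    return float(p)


def allelicmeth_profile(
    epireads: Sequence[Epiread],
) -> list[tuple[str, int, PairTable, float]]:
    """Linkage score at every adjacent CpG pair with spanning coverage.

    Returns (chrom, first CpG index of the pair, table, p-value) tuples,
    sorted; pairs with no spanning reads are absent.
    """
    tables: dict[tuple[str, int], list[int]] = {}
    for e in epireads:
        for k in range(len(e.states) - 1):
            key = (e.chrom, e.first_cpg_index + k)
            cell = tables.setdefault(key, [0, 0, 0, 0])
            a = e.states[k] == "C"
            b = e.states[k + 1] == "C"
            cell[(1 - a) * 2 + (1 - b)] += 1
    out = []
    for (chrom, idx) in sorted(tables):
        mm, mu, um, uu = tables[(chrom, idx)]
        table = PairTable(mm, mu, um, uu)
        p = allelic_score(table)
        assert p is not None  # pairs only exist with >= 1 spanning read
        out.append((chrom, idx, table, p))
    return out


# ---------------------------------------------------------------------------
# two-allele window model


@dataclass
class AmrWindowResult:
    """Model comparison in one window of consecutive CpGs."""

    window_start: int
    n_cpgs: int
    n_reads: int
    loglik_single: float
    loglik_two_allele: float
    p_value: float
    responsibilities: np.ndarray = field(repr=False)  # P(allele 1) per read
    em_trace: list[float] = field(default_factory=list, repr=False)
    testable: bool = True

    @property
    def lrt(self) -> float:
        return 2.0 * (self.loglik_two_allele - self.loglik_single)


def _single_theta(X: np.ndarray) -> np.ndarray:
    """Smoothed per-CpG level estimates of the one-allele model."""
    meth = (X == 1).sum(axis=0).astype(float)
    tot = meth + (X == 0).sum(axis=0)
    return (meth + 0.5) / (tot + 1.0)


def _mixture_ll(X: np.ndarray, theta: np.ndarray) -> tuple[float, np.ndarray]:
    """Observed-data log-likelihood of the equal-weight two-allele mixture.

    Returns (loglik, responsibilities P(allele 1 | read)).
    """
    is_c = (X == 1).astype(float)
    is_t = (X == 0).astype(float)
    log_l = np.stack(
        [is_c @ np.log(theta[a]) + is_t @ np.log1p(-theta[a]) for a in (0, 1)]
    )
    ll = float(np.logaddexp(log_l[0], log_l[1]).sum()) + X.shape[0] * np.log(0.5)
    resp = 1.0 / (1.0 + np.exp(log_l[1] - log_l[0]))
    return ll, resp


def _em_mixture(
    X: np.ndarray, resp0: np.ndarray, max_iter: int = 50, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """EM for the two-allele mixture with fixed 1/2 mixing weights.

    Per-CpG levels take smoothed updates (posterior mean under a uniform
    prior); the returned trace is the penalized objective the updates
    maximize, which is non-decreasing.  Returns (theta, resp, trace).
    """
    is_c = (X == 1).astype(float)
    is_t = (X == 0).astype(float)
    resp = resp0.copy()
    theta = np.empty((2, X.shape[1]))
    trace: list[float] = []
    for _ in range(max_iter):
        w = np.stack([resp, 1 - resp])
        for a in (0, 1):
            meth = w[a] @ is_c
            tot = w[a] @ (is_c + is_t)
            theta[a] = (meth + 0.5) / (tot + 1.0)
        ll, resp = _mixture_ll(X, theta)
        # the smoothed M-step maximizes the Beta(3/2, 3/2)-penalized
        # objective, so that is the monotone quantity the trace records
        penalty = 0.5 * float(np.log(theta).sum() + np.log1p(-theta).sum())
        trace.append(ll + penalty)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            break
    return theta, resp, trace


def fit_amr_window(
    epireads: Sequence[Epiread],
    n_cpgs: int = 10,
    window_start: int = 0,
    min_reads: int = 10,
    n_restarts: int = 5,
    seed: int | None = 0,
) -> AmrWindowResult:
    """Compare the one-allele and two-allele models in one CpG window.

    Reads are clipped to [window_start, window_start + n_cpgs); windows with
    fewer than ``min_reads`` overlapping reads are flagged untestable
    (p = 1).  The two-allele likelihood is the mixture likelihood at the
    best EM solution across restarts (random splits plus a split on the
    first covered CpG); the degenerate equal-profiles configuration, whose
    mixture likelihood equals the one-allele likelihood exactly, is always
    a candidate, so loglik_two_allele never falls below loglik_single.
    """
    rng = np.random.default_rng(seed)
    w_end = window_start + n_cpgs
    rows = []
    for e in epireads:
        s = max(e.first_cpg_index, window_start)
        t = min(e.first_cpg_index + len(e.states), w_end)
        if s >= t:
            continue
        row = np.full(n_cpgs, -1, dtype=np.int8)
        for idx in range(s, t):
            row[idx - window_start] = 1 if e.states[idx - e.first_cpg_index] == "C" else 0
        rows.append(row)
    X = np.array(rows, dtype=np.int8) if rows else np.empty((0, n_cpgs), dtype=np.int8)
    n_reads = X.shape[0]

    theta1 = _single_theta(X)
    is_c = (X == 1).astype(float)
    is_t = (X == 0).astype(float)
    ll_single = float((is_c @ np.log(theta1) + is_t @ np.log1p(-theta1)).sum())

    if n_reads < min_reads:
        return AmrWindowResult(
            window_start, n_cpgs, n_reads, ll_single, ll_single, 1.0,
            np.zeros(n_reads), [], testable=False,
        )

    # EM from several starts; equal profiles reproduce the one-allele fit
    best_ll = ll_single
    best_resp = np.full(n_reads, 0.5)
    best_trace: list[float] = []
    starts = []
    covered_cols = np.where((X >= 0).any(axis=0))[0]
    if covered_cols.size:
        first = covered_cols[0]
        starts.append((X[:, first] == 1).astype(float))  # split on first covered CpG
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(rng.random(n_reads))
    for resp0 in starts:
        theta, resp, trace = _em_mixture(X, np.asarray(resp0, dtype=float))
        ll, resp = _mixture_ll(X, theta)
        if ll > best_ll:
            best_ll = ll
            best_resp = resp
            best_trace = trace

    lrt = 2.0 * (best_ll - ll_single)
    p = float(stats.chi2.sf(lrt, df=n_cpgs))
    return AmrWindowResult(
        window_start, n_cpgs, n_reads, ll_single, best_ll, p, best_resp, best_trace
    )


def call_amrs(
    epireads: Sequence[Epiread],
    cpg_positions: np.ndarray | None = None,
    window_cpgs: int = 10,
    min_reads: int = 10,
    fdr: float = 0.05,
    n_restarts: int = 5,
    seed: int | None = 0,
) -> list[GenomicFeature]:
    """Slide the two-allele test over the genome and merge significant windows.

    Windows step by one CpG; p-values of testable windows are corrected by
    Benjamini-Hochberg at level ``fdr``; overlapping significant windows
    merge into AMR features.  ``cpg_positions`` maps CpG indices to genomic
    coordinates (feature end = last CpG position + 1); with None, CpG
    indices are used directly.
    """
    by_chrom: dict[str, list[Epiread]] = {}
    for e in epireads:
        by_chrom.setdefault(e.chrom, []).append(e)

    features: list[GenomicFeature] = []
    for chrom in sorted(by_chrom):
        reads = sorted(by_chrom[chrom], key=lambda e: e.first_cpg_index)
        n_total = max(e.last_cpg_index for e in reads) + 1
        if cpg_positions is not None and n_total > len(cpg_positions):
            raise ValueError("epireads index beyond the CpG position map")
        read_starts = np.array([e.first_cpg_index for e in reads])
        read_ends = np.array([e.last_cpg_index + 1 for e in reads])

        results: list[AmrWindowResult] = []
        for w0 in range(0, max(n_total - window_cpgs, 0) + 1):
            sel = (read_starts < w0 + window_cpgs) & (read_ends > w0)
            if not sel.any():
                continue
            window_reads = [reads[i] for i in np.where(sel)[0]]
            res = fit_amr_window(
                window_reads, window_cpgs, w0, min_reads, n_restarts, seed
            )
            if res.testable:
                results.append(res)
        if not results:
            continue
        pvals = np.array([r.p_value for r in results])
        reject, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")[:1]

        sig = [r for r, rj in zip(results, reject) if rj]
        sig.sort(key=lambda r: r.window_start)
        i = 0
        while i < len(sig):
            j = i
            last_idx = sig[i].window_start + window_cpgs - 1
            while j + 1 < len(sig) and sig[j + 1].window_start <= last_idx + 1:
                j += 1
                last_idx = max(last_idx, sig[j].window_start + window_cpgs - 1)
            first_idx = sig[i].window_start
            if cpg_positions is not None:
                start = int(cpg_positions[first_idx])
                end = int(cpg_positions[min(last_idx, len(cpg_positions) - 1)]) + 1
            else:
                start, end = first_idx, last_idx + 1
            features.append(
                GenomicFeature(
                    chrom, start, end,
                    name=f"AMR{len(features)}",
                    score=last_idx - first_idx + 1,
                )
            )
            i = j + 1
    return features
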