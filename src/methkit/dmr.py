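"""Differential methylation between two methylomes.

Per-CpG differential scores come first: at a site with counts (m_a, t_a)
and (m_b, t_b), the score is the posterior probability that sample A's
methylation level exceeds sample B's, computed by an exact finite Beta sum.
By Altham's classical equivalence this probability is exactly one minus the
one-sided Fisher exact p-value of the corresponding 2x2 table, so the score
weighs both the observed frequencies and the amount of data behind them: a
2/2 vs 0/2 difference scores 5/6, while the same frequencies at high depth
approach 1.

Two region callers consume the scores:

* the fragment method (:func:`hmr_fragments` + :func:`call_dmrs_fragment`)
  is HMR-centric: the contiguous parts of the symmetric difference of the
  two samples' HMR sets are candidate DMRs, called when they contain enough
  directionally consistent significant CpGs and enough covered CpGs in both
  samples (so a missing HMR is evidence, not lack of data);

* the HMM method (:func:`call_dmrs_hmm`) segments the per-CpG score
  sequence with a three-state HMM (no difference / A over B / B over A,
  Beta emissions over the scores) and is therefore sensitive to partial
  methylation differences that produce no HMR in either sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betaln

from .hmr import forward_backward, split_chains
from .io import CytosineRecord, GenomicFeature

__all__ = [
    "diff_score",
    "diff_scores",
    "hmr_fragments",
    "call_dmrs_fragment",
    "call_dmrs_hmm",
]


def diff_score(m_a: int, t_a: int, m_b: int, t_b: int) -> float | None:
    """Exact posterior probability that level_A exceeds level_B.

    Evaluates P(p_A > p_B) for p_A ~ Beta(m_a, u_a + 1) and
    p_B ~ Beta(m_b + 1, u_b) — the prior assignment under which the
    probability coincides exactly with one minus the one-sided Fisher
    exact p-value of the table [[m_a, u_a], [m_b, u_b]] (Altham).  Returns
    None when either site is uncovered.  Exact (finite sum in log space).
    """
    if not (0 <= m_a <= t_a and 0 <= m_b <= t_b):
        raise ValueError("require 0 <= m <= t for both samples")
    if t_a == 0 or t_b == 0:
        return None
    u_a, u_b = t_a - m_a, t_b - m_b
    if m_a == 0 or u_b == 0:
        return 0.0  # p_A has an atom at 0 / p_B at 1
    a1, b1 = float(m_a), float(u_a + 1)  # p_A shapes
    a2, b2 = float(m_b + 1), float(u_b)  # p_B shapes
    j = np.arange(m_a)
    terms = (
        betaln(a2 + j, b2 + b1)
        - np.log(b1 + j)
        - betaln(1 + j, b1)
        - betaln(a2, b2)
    )
    return float(np.exp(terms).sum())


@dataclass
class ScoredSite:
    """Both directional scores at one site.

    ``score`` = P(level_A > level_B), ``score_rev`` = P(level_B > level_A);
    the two do not sum to 1 — the gap is the discrete tie mass, and only
    the upper tail of each is calibrated (score > 1 - a has null
    probability <= a, by the Fisher equivalence).  ``mid`` symmetrizes by
    splitting the tie mass and is exactly antisymmetric under sample swap.
    """

    chrom: str
    pos: int
    score: float
    score_rev: float

    @property
    def mid(self) -> float:
        return 0.5 * (1.0 + self.score - self.score_rev)


def diff_scores(
    records_a: Sequence[CytosineRecord], records_b: Sequence[CytosineRecord]
) -> list[ScoredSite]:
    """Per-CpG differential scores at sites covered in both samples.

    Sites uncovered in either sample are treated as missing and omitted.
    """
    by_pos_b = {(r.chrom, r.pos): r for r in records_b}
    out: list[ScoredSite] = []
    for ra in records_a:
        rb = by_pos_b.get((ra.chrom, ra.pos))
        if rb is None:
            continue
        s = diff_score(ra.meth, ra.total, rb.meth, rb.total)
        if s is None:
            continue
        s_rev = diff_score(rb.meth, rb.total, ra.meth, ra.total)
        out.append(ScoredSite(ra.chrom, ra.pos, s, s_rev))
    return out


# ---------------------------------------------------------------------------
# fragment (HMR-centric) method


def hmr_fragments(
    hmrs_a: Sequence[GenomicFeature], hmrs_b: Sequence[GenomicFeature]
) -> list[GenomicFeature]:
    """Contiguous parts of the symmetric difference of two HMR sets.

    Each fragment is covered by exactly one sample's HMRs; the name field
    records the origin ("A" or "B").  Fragments are disjoint and sorted,
    and their union is exactly the symmetric difference.
    """
    chroms = sorted({f.chrom for f in hmrs_a} | {f.chrom for f in hmrs_b})
    fragments: list[GenomicFeature] = []
    for chrom in chroms:
        events: list[tuple[int, int, int]] = []  # (pos, +-1, which-set)
        for which, feats in ((0, hmrs_a), (1, hmrs_b)):
            for f in feats:
                if f.chrom != chrom:
                    continue
                events.append((f.start, 1, which))
                events.append((f.end, -1, which))
        events.sort()
        depth = [0, 0]
        prev = None
        for pos, delta, which in events:
            if prev is not None and pos > prev:
                in_a, in_b = depth[0] > 0, depth[1] > 0
                if in_a != in_b:
                    fragments.append(
                        GenomicFeature(
                            chrom, prev, pos, name="A" if in_a else "B"
                        )
                    )
            depth[which] += delta
            prev = pos
    # merge touching fragments of the same origin (caller sets are
    # non-overlapping, but bookkeeping can split at internal boundaries)
    merged: list[GenomicFeature] = []
    for f in fragments:
        if (
            merged
            and merged[-1].chrom == f.chrom
            and merged[-1].end == f.start
            and merged[-1].name == f.name
        ):
            merged[-1].end = f.end
        else:
            merged.append(f)
    return merged


def call_dmrs_fragment(
    fragments: Sequence[GenomicFeature],
    scores: Sequence[ScoredSite],
    alpha: float = 0.05,
    min_sig_cpgs: int = 5,
    min_covered: int = 10,
) -> list[GenomicFeature]:
    """Evaluate HMR-difference fragments against the per-CpG scores.

    A fragment originating from sample A (A has the HMR, so A is hypo
    there) requires CpGs with score_rev > 1 - alpha — significant evidence
    that level_B > level_A; B-fragments require score > 1 - alpha.  (Each
    direction uses its own calibrated upper tail; the lower tail of the
    opposite score is inflated by tie mass and is never used.)  Fragments
    with fewer than ``min_covered`` CpGs scored (covered in both samples)
    are dropped as lack-of-data rather than called.  The score column of a
    called DMR is its count of significant CpGs.
    """
    out: list[GenomicFeature] = []
    for frag in fragments:
        inside = [
            s
            for s in scores
            if s.chrom == frag.chrom and frag.start <= s.pos < frag.end
        ]
        if len(inside) < min_covered:
            continue
        if frag.name == "A":
            n_sig = sum(s.score_rev > 1 - alpha for s in inside)
            direction = "A_hypo"
        else:
            n_sig = sum(s.score > 1 - alpha for s in inside)
            direction = "B_hypo"
        if n_sig >= min_sig_cpgs:
            out.append(
                GenomicFeature(
                    frag.chrom, frag.start, frag.end,
                    name=f"DMR_{direction}", score=n_sig,
                )
            )
    return out


# ---------------------------------------------------------------------------
# three-state HMM method (dmr2)


def call_dmrs_hmm(
    scores: Sequence[ScoredSite],
    alpha: float = 0.05,
    min_sig_cpgs: int = 10,
    desert_size: int | None = 1000,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> list[GenomicFeature]:
    """Segment the per-CpG score sequence with a three-state HMM.

    Each site is reduced to a significance category: A-significant
    (score > 1 - alpha), B-significant (score_rev > 1 - alpha), or
    neither; by the Fisher calibration each directional category has null
    probability at most alpha.  Three states with categorical emissions
    segment the sequence: 0 = no difference (both directions rare), 1 = an
    over-abundance of A-significant sites, 2 = of B-significant sites.
    Emissions, transitions and the initial distribution are trained by
    Baum-Welch (closed-form M-steps; state identities re-ordered by
    directional excess after each step).  Decoded directional runs become
    DMRs when they contain at least ``min_sig_cpgs`` CpGs significant in
    the matching direction; direction is recorded in the name field and
    the significant-CpG count in the score column.  Requires >= 100
    scored CpGs.
    """
    if len(scores) < 100:
        raise ValueError(f"need >= 100 scored CpGs, got {len(scores)}")
    chroms = np.array([s.chrom for s in scores])
    pos = np.array([s.pos for s in scores], dtype=np.int64)
    sig_ab = np.array([s.score > 1 - alpha for s in scores])
    sig_ba = np.array([s.score_rev > 1 - alpha for s in scores])
    cats = np.where(sig_ab, 0, np.where(sig_ba, 1, 2))
    chains = split_chains(chroms, pos, desert_size)

    # emission[s, c] = P(category c | state s)
    emissions = np.array(
        [[alpha, alpha, 1 - 2 * alpha], [0.5, 0.02, 0.48], [0.02, 0.5, 0.48]]
    )
    trans = np.full((3, 3), 0.005) + np.eye(3) * 0.99
    init = np.array([0.9, 0.05, 0.05])

    prev_ll = -np.inf
    gamma = np.empty((len(cats), 3))
    for _ in range(max_iter):
        logB = np.log(emissions[:, cats]).T  # (n, 3)
        ll_total = 0.0
        xi = np.zeros((3, 3))
        g0 = np.zeros(3)
        for a0, b0 in chains:
            ll, g, xs = forward_backward(logB[a0:b0], trans, init)
            ll_total += ll
            gamma[a0:b0] = g
            xi += xs
            g0 += g[0]
        trans = xi / np.maximum(xi.sum(axis=1, keepdims=True), 1e-300)
        init = g0 / g0.sum()
        counts = np.stack(
            [gamma[cats == c].sum(axis=0) for c in (0, 1, 2)], axis=1
        )  # (3 states, 3 categories)
        emissions = np.maximum(counts, 1e-6)
        emissions /= emissions.sum(axis=1, keepdims=True)
        # keep identities by directional excess e[s,0] - e[s,1]
        excess = emissions[:, 0] - emissions[:, 1]
        order = list(np.argsort(excess))  # most-B, middle, most-A
        perm = [order[1], order[2], order[0]]
        if perm != [0, 1, 2]:
            emissions = emissions[perm]
            trans = trans[np.ix_(perm, perm)]
            init = init[perm]
        if abs(ll_total - prev_ll) / (abs(prev_ll) + 1e-12) < tol:
            break
        prev_ll = ll_total

    logB = np.log(emissions[:, cats]).T
    for a0, b0 in chains:
        _, g, _ = forward_backward(logB[a0:b0], trans, init)
        gamma[a0:b0] = g

    decoded = gamma.argmax(axis=1)
    features: list[GenomicFeature] = []
    for state, direction in ((1, "A_over_B"), (2, "B_over_A")):
        in_state = decoded == state
        for a0, b0 in chains:
            i = a0
            while i < b0:
                if in_state[i]:
                    j = i
                    while j + 1 < b0 and in_state[j + 1]:
                        j += 1
                    sig = sig_ab if state == 1 else sig_ba
                    n_sig = int(sig[i : j + 1].sum())
                    if n_sig >= min_sig_cpgs:
                        features.append(
                            GenomicFeature(
                                str(chroms[i]), int(pos[i]), int(pos[j]) + 1,
                                name=f"DMR_{direction}", score=n_sig,
                            )
                        )
                    i = j + 1
                else:
                    i += 1
    features.sort(key=lambda f: (f.chrom, f.start))
    return features
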