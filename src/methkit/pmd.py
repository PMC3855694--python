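"""Partially methylated domain (PMD) calling.

PMDs are domains of intermediate, disordered methylation spanning tens to
hundreds of kilobases, characteristic of immortalized cell lines, cancers
and placenta.  Their scale calls for a hierarchical strategy:

1. pool methylated / total counts of CpG-sym sites into non-overlapping
   bins (default 1 kb) and segment the bin sequence with a two-state
   beta-binomial HMM (background vs partially methylated), giving domain
   locations at bin resolution;
2. refine each domain boundary, which must lie within the two bins
   straddling the coarse bin edge, by a single change-point scan: the
   inter-site breakpoint maximizing the two-segment binomial log-likelihood
   over the one-segment model.  Boundaries whose likelihood gain is below a
   threshold stay at the bin edge.

The refined domains are filtered by a minimum size (default 10 kb).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hmr import (
    BetaBinomialParams,
    HmmParams,
    _em_two_state,
    _posteriors_two_state,
    records_to_arrays,
)
from .io import CytosineRecord, GenomicFeature

__all__ = [
    "BinnedCounts",
    "bin_counts",
    "call_pmds_coarse",
    "refine_boundary",
    "call_pmds",
]


@dataclass
class BinnedCounts:
    """Tiling non-overlapping bins with pooled counts per bin."""

    bin_size: int
    chroms: np.ndarray  # bin chromosome names
    starts: np.ndarray  # bin start positions
    meth: np.ndarray  # pooled methylated counts
    total: np.ndarray  # pooled total counts
    n_sites: np.ndarray  # CpG sites per bin

    def __len__(self) -> int:
        return len(self.starts)


def bin_counts(records: Sequence[CytosineRecord], bin_size: int = 1000) -> BinnedCounts:
    """Pool record counts into tiling bins of ``bin_size`` bp per chromosome.

    Empty bins are retained (conservation: bin sums equal record sums).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chroms, pos, m, t = records_to_arrays(records)
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_m: list[int] = []
    out_t: list[int] = []
    out_n: list[int] = []
    for chrom in dict.fromkeys(chroms.tolist()):  # preserve record order
        mask = chroms == chrom
        p, mm, tt = pos[mask], m[mask], t[mask]
        n_bins = int(p.max() // bin_size) + 1
        idx = p // bin_size
        bm = np.bincount(idx, weights=mm, minlength=n_bins).astype(np.int64)
        bt = np.bincount(idx, weights=tt, minlength=n_bins).astype(np.int64)
        bn = np.bincount(idx, minlength=n_bins).astype(np.int64)
        out_chrom.extend([chrom] * n_bins)
        out_start.extend(range(0, n_bins * bin_size, bin_size))
        out_m.extend(bm.tolist())
        out_t.extend(bt.tolist())
        out_n.extend(bn.tolist())
    return BinnedCounts(
        bin_size,
        np.array(out_chrom),
        np.array(out_start, dtype=np.int64),
        np.array(out_m, dtype=np.int64),
        np.array(out_t, dtype=np.int64),
        np.array(out_n, dtype=np.int64),
    )


def _default_bin_init() -> HmmParams:
    # background ~0.85, PMD ~0.45: the PMD state is intermediate, not hypo
    return HmmParams(
        trans=np.array([[0.99, 0.01], [0.01, 0.99]]),
        init=np.array([0.5, 0.5]),
        emissions=(BetaBinomialParams(17.0, 3.0), BetaBinomialParams(9.0, 11.0)),
    )


def call_pmds_coarse(
    bins: BinnedCounts,
    init: HmmParams | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    min_separation: float = 0.1,
) -> tuple[list[GenomicFeature], HmmParams]:
    """Two-state HMM over bins; returns coarse PMD features at bin resolution.

    State 1 (lower emission mean, initialized at partial methylation) is the
    PMD state; decoded maximal runs of PMD bins become features spanning
    whole bins.  Requires at least 10 non-empty bins.  When the trained
    emission means end up closer than ``min_separation`` the genome carries
    no partially methylated state and no features are returned — on a
    homogeneous methylome the two states collapse onto one level and any
    decoding of them is noise.
    """
    if int(np.sum(bins.total > 0)) < 10:
        raise ValueError("need at least 10 non-empty bins to segment")
    if init is None:
        init = _default_bin_init()
    params, _ = _em_two_state(
        bins.chroms, bins.starts, bins.meth, bins.total, init, tol, max_iter, None
    )
    if params.emissions[0].mean - params.emissions[1].mean < min_separation:
        return [], params
    gamma, chains = _posteriors_two_state(
        bins.chroms, bins.starts, bins.meth, bins.total, params, None
    )
    in_pmd = gamma[:, 1] > 0.5
    features: list[GenomicFeature] = []
    for a, b in chains:
        i = a
        while i < b:
            if in_pmd[i]:
                j = i
                while j + 1 < b and in_pmd[j + 1]:
                    j += 1
                features.append(
                    GenomicFeature(
                        chrom=str(bins.chroms[i]),
                        start=int(bins.starts[i]),
                        end=int(bins.starts[j]) + bins.bin_size,
                        name=f"PMD{len(features)}",
                        score=int(bins.n_sites[i : j + 1].sum()),
                    )
                )
                i = j + 1
            else:
                i += 1
    return features, params


def _binom_ll(m: int, t: int) -> float:
    if t == 0 or m == 0 or m == t:
        return 0.0
    p = m / t
    return m * np.log(p) + (t - m) * np.log1p(-p)


def refine_boundary(
    positions: np.ndarray,
    meth: np.ndarray,
    total: np.ndarray,
    gain_threshold: float = 2.0,
) -> tuple[int | None, float]:
    """Single change-point scan over the sites of the two flanking bins.

    Scans every inter-site breakpoint, scoring the gain of the two-segment
    binomial maximum likelihood over the one-segment model, and returns
    (position of the first site right of the best breakpoint, gain).  A scan
    with fewer than 2 covered sites, or whose best gain is below
    ``gain_threshold`` (spurious change point), returns (None, gain) and
    the caller keeps the bin-edge boundary.
    """
    positions = np.asarray(positions)
    meth = np.asarray(meth, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    covered = total > 0
    if int(covered.sum()) < 2:
        return None, 0.0
    n = len(positions)
    cm = np.concatenate([[0], np.cumsum(meth)])
    ct = np.concatenate([[0], np.cumsum(total)])
    full = _binom_ll(int(cm[n]), int(ct[n]))
    best_gain = -np.inf
    best_k = None
    for k in range(1, n):  # split: sites [0, k) | [k, n)
        left = _binom_ll(int(cm[k]), int(ct[k]))
        right = _binom_ll(int(cm[n] - cm[k]), int(ct[n] - ct[k]))
        gain = left + right - full
        if gain > best_gain:
            best_gain = gain
            best_k = k
    if best_k is None or best_gain < gain_threshold:
        return None, float(max(best_gain, 0.0))
    return int(positions[best_k]), float(best_gain)


def call_pmds(
    records: Sequence[CytosineRecord],
    bin_size: int = 1000,
    min_size: int = 10_000,
    gain_threshold: float = 2.0,
    init: HmmParams | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> list[GenomicFeature]:
    """Hierarchical PMD caller: coarse binned HMM, then boundary refinement.

    Each coarse boundary is re-located within its two flanking bins by the
    change-point scan; refinement never moves a boundary outside those bins.
    Refined features shorter than ``min_size`` bp are dropped.
    """
    chroms, pos, m, t = records_to_arrays(records)
    bins = bin_counts(records, bin_size)
    coarse, _params = call_pmds_coarse(bins, init, tol, max_iter)

    refined: list[GenomicFeature] = []
    for feat in coarse:
        on_chrom = chroms == feat.chrom
        p, mm, tt = pos[on_chrom], m[on_chrom], t[on_chrom]

        def refine_at(edge: int) -> int:
            lo, hi = edge - bin_size, edge + bin_size
            window = (p >= lo) & (p < hi)
            if not window.any():
                return edge
            bp, _gain = refine_boundary(
                p[window], mm[window], tt[window], gain_threshold
            )
            return edge if bp is None else int(np.clip(bp, lo + 1, hi - 1))

        start = refine_at(feat.start)
        end = refine_at(feat.end)
        if end <= start:
            continue
        refined.append(
            GenomicFeature(feat.chrom, start, end, feat.name, feat.score, feat.strand)
        )

    # refinement can make neighbours touch; clip any residual overlap
    for i in range(1, len(refined)):
        a, b = refined[i - 1], refined[i]
        if a.chrom == b.chrom and b.start < a.end:
            b.start = a.end
    return [f for f in refined if f.end - f.start >= min_size]
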