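"""Per-cytosine methylation counting and summary statistics.

The counting step walks deduplicated, clipped reads against the reference:
at each reference C (informative in + strand reads) a C base is a methylated
observation and a T an unmethylated one; at each reference G (informative in
- strand reads, bases reported on the + strand) the roles are played by G
and A.  Any other base is a mismatch and ignored.  The level estimate at a
site is m / (m + u) — an unbiased estimate of the fraction of molecules in
the cell population carrying the methyl mark.

For the symmetric CpG context, the + strand C and - strand G of a dyad
measure the same methylation state, so their counts are pooled into a single
``CpG-sym`` record (:func:`merge_symmetric_cpgs`).

Region and genome-wide summaries (mean level, fraction of methylated sites,
coverage-weighted mean), Wilson confidence intervals for per-site levels,
and the coverage-vs-CpG-density QC correlation live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io import CytosineRecord, GenomicFeature, check_sorted_records
from .reads import MappedRead

__all__ = [
    "RegionLevels",
    "MethylomeSummary",
    "count_methylation",
    "merge_symmetric_cpgs",
    "level_confidence_interval",
    "region_levels",
    "methylome_summary",
    "coverage_density_correlation",
]


def _context_plus(seq: str, i: int) -> str:
    if i + 1 < len(seq) and seq[i + 1] == "G":
        return "CpG"
    if i + 2 < len(seq) and seq[i + 2] == "G":
        return "CHG"
    return "CHH"


def _context_minus(seq: str, i: int) -> str:
    # reverse-complement context of a reference G read 3'->5' on the - strand
    if i - 1 >= 0 and seq[i - 1] == "C":
        return "CpG"
    if i - 2 >= 0 and seq[i - 2] == "C":
        return "CHG"
    return "CHH"


def count_methylation(
    reads: Iterable[MappedRead],
    reference: Mapping[str, str],
    cpg_only: bool = False,
) -> list[CytosineRecord]:
    """Count methylated / unmethylated observations at every cytosine.

    Emits one record per reference C (strand '+') and G (strand '-'),
    including uncovered sites, sorted by position.  ``total`` is m + u;
    mismatching read bases contribute to neither.
    """
    ref_upper = {c: s.upper() for c, s in reference.items()}
    meth: dict[str, np.ndarray] = {}
    unmeth: dict[str, np.ndarray] = {}
    for chrom, seq in ref_upper.items():
        meth[chrom] = np.zeros(len(seq), dtype=np.int64)
        unmeth[chrom] = np.zeros(len(seq), dtype=np.int64)

    for read in reads:
        seq = ref_upper.get(read.chrom)
        if seq is None:
            raise ValueError(f"read {read.name}: unknown chromosome {read.chrom}")
        if read.end > len(seq) or read.start < 0:
            raise ValueError(
                f"read {read.name} extends past reference end of {read.chrom}"
            )
        for j, base in enumerate(read.bases):
            p = read.start + j
            ref_base = seq[p]
            if read.strand == "+" and ref_base == "C":
                if base == "C":
                    meth[read.chrom][p] += 1
                elif base == "T":
                    unmeth[read.chrom][p] += 1
            elif read.strand == "-" and ref_base == "G":
                if base == "G":
                    meth[read.chrom][p] += 1
                elif base == "A":
                    unmeth[read.chrom][p] += 1

    records: list[CytosineRecord] = []
    for chrom in sorted(ref_upper):
        seq = ref_upper[chrom]
        for i, ref_base in enumerate(seq):
            if ref_base == "C":
                strand, context = "+", _context_plus(seq, i)
            elif ref_base == "G":
                strand, context = "-", _context_minus(seq, i)
            else:
                continue
            if cpg_only and context != "CpG":
                continue
            m = int(meth[chrom][i])
            u = int(unmeth[chrom][i])
            records.append(CytosineRecord(chrom, i, strand, context, m, m + u))
    return records


def merge_symmetric_cpgs(records: Sequence[CytosineRecord]) -> list[CytosineRecord]:
    """Pool each CpG dyad (+ strand C at p, - strand G at p+1) into one
    ``CpG-sym`` record at p with summed counts.

    Unpaired CpG records are emitted alone as CpG-sym at the dyad's C
    position; non-CpG records pass through unchanged.  Idempotent, and
    conserves total methylated and total read counts over CpG records.
    """
    check_sorted_records(records)
    out: list[CytosineRecord] = []
    i = 0
    n = len(records)
    while i < n:
        r = records[i]
        if r.context == "CpG" and r.strand == "+":
            partner = records[i + 1] if i + 1 < n else None
            if (
                partner is not None
                and partner.chrom == r.chrom
                and partner.pos == r.pos + 1
                and partner.context == "CpG"
                and partner.strand == "-"
            ):
                out.append(
                    CytosineRecord(
                        r.chrom,
                        r.pos,
                        "+",
                        "CpG-sym",
                        r.meth + partner.meth,
                        r.total + partner.total,
                    )
                )
                i += 2
                continue
            out.append(CytosineRecord(r.chrom, r.pos, "+", "CpG-sym", r.meth, r.total))
        elif r.context == "CpG" and r.strand == "-":
            # orphan - strand G: place the merged record at the dyad C position
            pos = r.pos - 1 if r.pos > 0 else r.pos
            out.append(CytosineRecord(r.chrom, pos, "+", "CpG-sym", r.meth, r.total))
        else:
            out.append(r)
        i += 1
    return out


def level_confidence_interval(
    meth: int, total: int, conf: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for the methylation level at one site."""
    if total <= 0:
        raise ValueError("confidence interval undefined for uncovered site (t = 0)")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    lower, upper = proportion_confint(meth, total, alpha=1 - conf, method="wilson")
    return float(lower), float(upper)


@dataclass
class RegionLevels:
    """Methylation summaries of one region over CpG-sym sites.

    ``mean_level`` averages per-site levels; ``frac_meth`` is the share of
    covered sites called methylated (level above the threshold);
    ``weighted_mean`` pools counts (sum m / sum t), down-weighting
    low-coverage sites.  ``defined`` is False when no site is covered.
    """

    mean_level: float
    frac_meth: float
    weighted_mean: float
    n_covered: int
    n_total: int
    defined: bool


def region_levels(
    records: Sequence[CytosineRecord],
    region: GenomicFeature,
    meth_threshold: float = 0.5,
) -> RegionLevels:
    inside = [
        r
        for r in records
        if r.chrom == region.chrom and region.start <= r.pos < region.end
    ]
    covered = [r for r in inside if r.total > 0]
    if not covered:
        return RegionLevels(float("nan"), float("nan"), float("nan"), 0, len(inside), False)
    levels = np.array([r.level for r in covered])
    sum_m = sum(r.meth for r in covered)
    sum_t = sum(r.total for r in covered)
    return RegionLevels(
        mean_level=float(levels.mean()),
        frac_meth=float(np.mean(levels > meth_threshold)),
        weighted_mean=sum_m / sum_t,
        n_covered=len(covered),
        n_total=len(inside),
        defined=True,
    )


@dataclass
class MethylomeSummary:
    mean_coverage: float  # over all cytosine records
    mean_coverage_cpg: float  # over CpG/CpG-sym records only
    weighted_mean_level: float
    n_covered_cpg: int
    n_covered_cytosines: int
    n_sites: int


def methylome_summary(records: Sequence[CytosineRecord]) -> MethylomeSummary:
    """Genome-wide coverage and methylation summary.

    Mean coverage is reported both over all cytosines and over CpG sites
    only, since either denominator is in common use.
    """
    if not records:
        return MethylomeSummary(0.0, 0.0, 0.0, 0, 0, 0)
    t = np.array([r.total for r in records], dtype=float)
    m = np.array([r.meth for r in records], dtype=float)
    is_cpg = np.array([r.context in ("CpG", "CpG-sym") for r in records])
    total_reads = t.sum()
    return MethylomeSummary(
        mean_coverage=float(t.mean()),
        mean_coverage_cpg=float(t[is_cpg].mean()) if is_cpg.any() else 0.0,
        weighted_mean_level=float(m.sum() / total_reads) if total_reads > 0 else 0.0,
        n_covered_cpg=int(np.sum(is_cpg & (t > 0))),
        n_covered_cytosines=int(np.sum(t > 0)),
        n_sites=len(records),
    )


def coverage_density_correlation(
    records: Sequence[CytosineRecord],
    cpg_positions: Mapping[str, np.ndarray] | None = None,
    bin_size: int = 1000,
) -> tuple[float, float, int]:
    """Pearson correlation between CpG density and mean CpG coverage per bin.

    ``cpg_positions`` maps chromosome to the positions of all CpG sites
    (covered or not); by default the CpG/CpG-sym records themselves define
    the site list.  Bins with no CpG are skipped.  Returns (r, two-sided p,
    number of bins used); raises if fewer than 3 usable bins.
    """
    by_chrom: dict[str, list[CytosineRecord]] = {}
    for r in records:
        if r.context in ("CpG", "CpG-sym"):
            by_chrom.setdefault(r.chrom, []).append(r)
    densities: list[float] = []
    coverages: list[float] = []
    for chrom, recs in by_chrom.items():
        if cpg_positions is not None:
            positions = np.asarray(cpg_positions[chrom])
        else:
            positions = np.array([r.pos for r in recs])
        cov_by_pos = {r.pos: r.total for r in recs}
        if len(positions) == 0:
            continue
        n_bins = int(positions.max() // bin_size) + 1
        for b in range(n_bins):
            in_bin = positions[(positions >= b * bin_size) & (positions < (b + 1) * bin_size)]
            if len(in_bin) == 0:
                continue
            densities.append(len(in_bin))
            coverages.append(float(np.mean([cov_by_pos.get(int(p), 0) for p in in_bin])))
    if len(densities) < 3:
        raise ValueError(f"need >= 3 non-empty bins, got {len(densities)}")
    r, p = stats.pearsonr(densities, coverages)
    return float(r), float(p), len(densities)
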