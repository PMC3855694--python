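"""Read-level preprocessing for bisulfite sequencing data.

Covers the steps between mapping (out of scope) and per-cytosine counting:
PCR-duplicate removal, clipping of overlapping mate pairs so no position is
counted twice, and estimation of the bisulfite conversion rate from control
cytosines of known unmethylated status (spike-ins or mitochondrial DNA).

Reads are represented in reference coordinates with an ungapped base string
on the + strand of the reference (the SAM convention); paired-end mates are
separate reads.  Reads can be loaded from an 8-column tab-separated table
(chrom, start, end, strand, name, bases, quals as phred+33 string, library)
or from a SAM file via pysam (ungapped alignments only).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MappedRead",
    "BsRateResult",
    "remove_duplicates",
    "clip_mate_overlap",
    "estimate_bsrate",
    "read_mapped_reads",
    "write_mapped_reads",
]


@dataclass
class MappedRead:
    """A mapped bisulfite read (ungapped, reference + strand bases)."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    bases: str
    quals: list[int]
    library: str = "lib"

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.bases):
            raise ValueError(
                f"read {self.name}: span {self.end - self.start} != "
                f"{len(self.bases)} bases"
            )
        if len(self.quals) != len(self.bases):
            raise ValueError(f"read {self.name}: quals/bases length mismatch")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.name}: invalid strand {self.strand!r}")

    @property
    def key(self) -> tuple:
        """Duplicate key: identical mapping coordinates and strand."""
        return (self.chrom, self.start, self.end, self.strand)


def _check_sorted_reads(reads: Sequence[MappedRead]) -> None:
    for i in range(1, len(reads)):
        a, b = reads[i - 1], reads[i]
        if a.chrom == b.chrom and (a.start, a.end, a.strand) > (b.start, b.end, b.strand):
            raise ValueError(f"reads unsorted at index {i} ({b.name})")


def remove_duplicates(
    reads: Sequence[MappedRead], seed: int | None = None
) -> list[MappedRead]:
    """Keep one uniformly random read per (chrom, start, end, strand, library).

    Reads sharing mapping coordinates arise from PCR over-amplification of a
    single molecule; keeping a random representative avoids biasing level
    estimates toward over-amplified fragments.  Reads from different
    libraries are necessarily distinct molecules and never collapse.
    Requires input sorted by (chrom, start, end, strand); output preserves
    that order.  Idempotent.
    """
    _check_sorted_reads(reads)
    rng = np.random.default_rng(seed)
    out: list[MappedRead] = []
    i = 0
    n = len(reads)
    while i < n:
        j = i
        while j + 1 < n and reads[j + 1].key == reads[i].key:
            j += 1
        by_library: dict[str, list[MappedRead]] = defaultdict(list)
        for r in reads[i : j + 1]:
            by_library[r.library].append(r)
        for library in sorted(by_library):
            group = by_library[library]
            out.append(group[int(rng.integers(len(group)))])
        i = j + 1
    return out


def _trim(read: MappedRead, new_start: int, new_end: int) -> MappedRead | None:
    if new_start >= new_end:
        return None
    a = new_start - read.start
    b = new_end - read.start
    return replace(
        read,
        start=new_start,
        end=new_end,
        bases=read.bases[a:b],
        quals=read.quals[a:b],
    )


def clip_mate_overlap(
    mate1: MappedRead, mate2: MappedRead
) -> tuple[MappedRead | None, MappedRead | None]:
    """Clip the lower-quality mate where a pair overlaps.

    Quality of each mate over the overlapped interval is its summed base
    quality; ties clip mate2.  After clipping, no reference position is
    covered by both mates, preventing double counting of the same molecule.
    A mate whose bases are entirely within the overlap is dropped (None).
    Non-overlapping pairs are returned unchanged.
    """
    if mate1.chrom != mate2.chrom:
        raise ValueError(
            f"mates on different chromosomes: {mate1.chrom} vs {mate2.chrom}"
        )
    ov_start = max(mate1.start, mate2.start)
    ov_end = min(mate1.end, mate2.end)
    if ov_start >= ov_end:
        return mate1, mate2

    def qualsum(r: MappedRead) -> int:
        return sum(r.quals[ov_start - r.start : ov_end - r.start])

    clip_second = qualsum(mate2) <= qualsum(mate1)
    victim = mate2 if clip_second else mate1
    # remove the overlap from the victim; if the overlap is interior
    # (containment), the victim keeps only its part left of the overlap
    if ov_start > victim.start and ov_end < victim.end:
        clipped = _trim(victim, victim.start, ov_start)
    elif ov_start > victim.start:
        clipped = _trim(victim, victim.start, ov_start)
    else:
        clipped = _trim(victim, ov_end, victim.end)
    if clip_second:
        return mate1, clipped
    return clipped, mate2


@dataclass
class BsRateResult:
    """Conversion-rate estimate; ``rate`` is None when no control bases seen."""

    rate: float | None
    n_converted: int
    n_total: int


def estimate_bsrate(
    reads: Iterable[MappedRead],
    control_cytosines: Iterable[tuple[str, int, str]],
    exclude_cpg: Iterable[tuple[str, int]] = (),
) -> BsRateResult:
    """Bisulfite conversion rate from cytosines known to be unmethylated.

    ``control_cytosines`` are (chrom, pos, strand) triples: a '+' entry is a
    reference C informative in + strand reads (T = converted, C = not);
    a '-' entry is a reference G informative in - strand reads (A = converted,
    G = not, bases being reported on the + strand).  Positions listed in
    ``exclude_cpg`` are skipped, guarding against residual CpG methylation
    in the control sequence.
    """
    controls: dict[tuple[str, int], str] = {}
    excluded = set(exclude_cpg)
    for chrom, pos, strand in control_cytosines:
        if (chrom, pos) not in excluded:
            controls[(chrom, pos)] = strand
    n_conv = n_total = 0
    for read in reads:
        for pos in range(read.start, read.end):
            strand = controls.get((read.chrom, pos))
            if strand is None or strand != read.strand:
                continue
            base = read.bases[pos - read.start]
            if strand == "+":
                if base == "T":
                    n_conv += 1
                    n_total += 1
                elif base == "C":
                    n_total += 1
            else:
                if base == "A":
                    n_conv += 1
                    n_total += 1
                elif base == "G":
                    n_total += 1
    rate = n_conv / n_total if n_total > 0 else None
    return BsRateResult(rate, n_conv, n_total)


# ---------------------------------------------------------------------------
# I/O: 8-column table and SAM


def read_mapped_reads(path: str, fmt: str = "tsv") -> list[MappedRead]:
    """Load mapped reads from the 8-column table or a SAM file.

    SAM input uses pysam; only ungapped alignments (single M cigar) are
    accepted, the library is taken from the read group (RG tag) when present.
    """
    if fmt == "sam":
        return _read_sam(path)
    if fmt != "tsv":
        raise ValueError(f"unknown reads format {fmt!r}")
    reads: list[MappedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
            chrom, start_s, end_s, strand, name, bases, quals_s, library = fields
            try:
                reads.append(
                    MappedRead(
                        chrom,
                        int(start_s),
                        int(end_s),
                        strand,
                        name,
                        bases,
                        [ord(c) - 33 for c in quals_s],
                        library,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return reads


def write_mapped_reads(reads: Sequence[MappedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.quals)
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.name}\t"
                f"{r.bases}\t{quals}\t{r.library}\n"
            )


def _read_sam(path: str) -> list[MappedRead]:
    import pysam

    reads: list[MappedRead] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            cigar = aln.cigartuples or []
            if len(cigar) != 1 or cigar[0][0] != 0:  # single M only
                raise ValueError(
                    f"read {aln.query_name}: only ungapped alignments supported"
                )
            library = "lib"
            if aln.has_tag("RG"):
                library = str(aln.get_tag("RG"))
            quals = (
                list(aln.query_qualities)
                if aln.query_qualities is not None
                else [40] * len(aln.query_sequence)
            )
            reads.append(
                MappedRead(
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_start + len(aln.query_sequence),
                    strand="-" if aln.is_reverse else "+",
                    name=aln.query_name,
                    bases=aln.query_sequence.upper(),
                    quals=quals,
                    library=library,
                )
            )
    return reads
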