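"""Domain types and text-format I/O for methylome data.

Three plain-text formats are supported, all 0-based and half-open:

* **counts** — one cytosine per line, six whitespace-separated columns:
  ``chrom pos strand context level total``.  ``level`` is the estimated
  methylation level (methylated reads / total reads) written with six
  decimal places; the methylated-read count is reconstructed as
  ``round(level * total)``.
* **BED** — BED3 to BED6 accepted on input, BED6 written on output.
  Feature callers put a caller-specific score (typically the number of
  CpGs supporting the feature) in column 5.
* **epireads** — one read per line: ``chrom first_cpg_index states``,
  where ``states`` is a string over ``C`` (methylated) / ``T``
  (unmethylated) giving the read's calls at consecutive CpG sites,
  indexed into the ordered CpG list of the chromosome.

Records are kept sorted by (chromosome block, position); functions here
raise on unsorted input rather than silently resorting, so ordering bugs
surface at the boundary where they are introduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CytosineRecord",
    "GenomicFeature",
    "Epiread",
    "CONTEXTS",
    "read_counts",
    "write_counts",
    "read_bed",
    "write_bed",
    "read_epireads",
    "write_epireads",
    "check_sorted_records",
    "interval_jaccard",
    "feature_recall_precision",
]

CONTEXTS = frozenset({"CpG", "CHG", "CHH", "CpG-sym"})

_STRANDS = frozenset({"+", "-"})
_FEATURE_STRANDS = frozenset({"+", "-", "."})


@dataclass
class CytosineRecord:
    """One cytosine site with its methylated / total read counts.

    ``pos`` is the 0-based position of the cytosine on the + strand of the
    reference; after symmetric merging a CpG dyad is represented by a single
    ``CpG-sym`` record at the position of the C on the + strand.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    meth: int
    total: int

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")
        if not (0 <= self.meth <= self.total):
            raise ValueError(
                f"invalid counts meth={self.meth} total={self.total} at "
                f"{self.chrom}:{self.pos}"
            )

    @property
    def level(self) -> float:
        """Methylation level m/t; 0.0 for uncovered sites (t == 0)."""
        return self.meth / self.total if self.total > 0 else 0.0

    @property
    def covered(self) -> bool:
        return self.total > 0


@dataclass
class GenomicFeature:
    """A called interval (HMR / HyperMR / PMD / AMR / DMR), BED-style."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _FEATURE_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Epiread:
    """Per-read methylation states over consecutive CpGs of one chromosome."""

    chrom: str
    first_cpg_index: int
    states: str

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("epiread states must be non-empty")
        if set(self.states) - {"C", "T"}:
            raise ValueError(f"epiread states contain invalid symbols: {self.states!r}")
        if self.first_cpg_index < 0:
            raise ValueError("first_cpg_index must be non-negative")

    @property
    def n_cpgs(self) -> int:
        return len(self.states)

    @property
    def last_cpg_index(self) -> int:
        return self.first_cpg_index + len(self.states) - 1


# ---------------------------------------------------------------------------
# sortedness checks


def check_sorted_records(records: Sequence[CytosineRecord]) -> None:
    """Raise ValueError unless records are sorted by (chrom block, pos)."""
    seen: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = -1
    for i, r in enumerate(records):
        if r.chrom != prev_chrom:
            if r.chrom in seen:
                raise ValueError(f"records unsorted: chromosome {r.chrom} re-appears")
            seen.add(r.chrom)
            prev_chrom = r.chrom
            prev_pos = -1
        if r.pos <= prev_pos:
            raise ValueError(
                f"records unsorted at index {i}: {r.chrom}:{r.pos} after {prev_pos}"
            )
        prev_pos = r.pos


def _check_sorted_features(features: Sequence[GenomicFeature]) -> None:
    for i in range(1, len(features)):
        a, b = features[i - 1], features[i]
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"features overlap or are unsorted at index {i}: "
                f"{a.chrom}:{a.start}-{a.end} vs {b.chrom}:{b.start}-{b.end}"
            )


# ---------------------------------------------------------------------------
# counts files


def read_counts(path: str) -> list[CytosineRecord]:
    """Read a 6-column counts file into sorted CytosineRecords.

    The methylated count is reconstructed as ``round(level * total)``, which
    is exact for levels written at 6 decimals with totals below ~10^5.
    """
    records: list[CytosineRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom, pos_s, strand, context, level_s, total_s = fields
            try:
                pos = int(pos_s)
                level = float(level_s)
                total = int(total_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from None
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"{path}:{lineno}: level {level} outside [0, 1]")
            meth = int(math.floor(level * total + 0.5))
            try:
                records.append(
                    CytosineRecord(chrom, pos, strand, context, meth, total)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    try:
        check_sorted_records(records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
    return records


def write_counts(records: Sequence[CytosineRecord], path: str) -> None:
    check_sorted_records(records)
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.context}\t{r.level:.6f}\t{r.total}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str) -> list[GenomicFeature]:
    features: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            chrom, start_s, end_s = fields[:3]
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else 0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                features.append(
                    GenomicFeature(chrom, int(start_s), int(end_s), name, score, strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return features


def _fmt_score(score: float) -> str:
    if float(score) == int(score):
        return str(int(score))
    return f"{score:g}"


def write_bed(features: Sequence[GenomicFeature], path: str) -> None:
    _check_sorted_features(features)
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t{_fmt_score(f.score)}\t{f.strand}\n"
            )


# ---------------------------------------------------------------------------
# epireads


def read_epireads(path: str) -> list[Epiread]:
    epireads: list[Epiread] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            chrom, idx_s, states = fields
            try:
                epireads.append(Epiread(chrom, int(idx_s), states))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return epireads


def write_epireads(epireads: Sequence[Epiread], path: str) -> None:
    with open(path, "w") as fh:
        for e in epireads:
            fh.write(f"{e.chrom}\t{e.first_cpg_index}\t{e.states}\n")


# ---------------------------------------------------------------------------
# interval utilities shared by callers and tests


def _merged_intervals(features: Iterable[GenomicFeature]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out[chrom] = merged
    return out


def _overlap_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def interval_jaccard(
    features_a: Iterable[GenomicFeature], features_b: Iterable[GenomicFeature]
) -> float:
    """Base-pair Jaccard index between two interval sets (1.0 if both empty)."""
    a = _merged_intervals(features_a)
    b = _merged_intervals(features_b)
    inter = 0
    len_a = sum(e - s for ivs in a.values() for s, e in ivs)
    len_b = sum(e - s for ivs in b.values() for s, e in ivs)
    for chrom in set(a) & set(b):
        inter += _overlap_bp(a[chrom], b[chrom])
    union = len_a + len_b - inter
    if union == 0:
        return 1.0
    return inter / union


def feature_recall_precision(
    called: Sequence[GenomicFeature],
    truth: Sequence[GenomicFeature],
    min_frac: float = 0.5,
) -> tuple[float, float]:
    """Feature-level recall and precision by reciprocal-free overlap.

    A truth feature counts as recovered when called intervals cover at least
    ``min_frac`` of its length; a called feature counts as a true positive
    when truth intervals cover at least ``min_frac`` of its length.  Returns
    (recall, precision); an empty reference side yields 1.0 for that metric.
    """
    called_iv = _merged_intervals(called)
    truth_iv = _merged_intervals(truth)

    def frac_covered(f: GenomicFeature, ivs: dict[str, list[tuple[int, int]]]) -> float:
        cov = _overlap_bp([(f.start, f.end)], ivs.get(f.chrom, []))
        return cov / (f.end - f.start)

    recall = (
        sum(frac_covered(f, called_iv) >= min_frac for f in truth) / len(truth)
        if truth
        else 1.0
    )
    precision = (
        sum(frac_covered(f, truth_iv) >= min_frac for f in called) / len(called)
        if called
        else 1.0
    )
    return recall, precision
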