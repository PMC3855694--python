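"""Synthetic methylome generator with planted ground truth.

Every downstream stage of the toolkit can be exercised on data from this
module: per-cytosine counts with planted hypo-/hyper-methylated features
(:func:`simulate_methylome`), read-level CpG state strings with planted
allele-specific regions (:func:`simulate_epireads`), duplicated mapped-read
sets (:func:`simulate_duplicated_reads`) and bisulfite reads over an
explicit reference (:func:`simulate_bs_reads`).

The generative assumptions deliberately mirror the segmentation models:
CpG positions are laid down with geometric gaps, feature and background run
lengths (in CpGs) are geometric, per-site coverage is Poisson, and
methylated counts are beta-binomial given the hidden state.  Feature blocks
may contain short embedded low-methylation runs, which emulates the mosaic
(plant-like) methylomes targeted by the three-state HyperMR model.  All
randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hmr import BetaBinomialParams
from .io import CytosineRecord, Epiread, GenomicFeature
from .reads import MappedRead

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_methylome",
    "simulate_epireads",
    "simulate_duplicated_reads",
    "simulate_bs_reads",
    "HMR_SIM",
    "HYPERMR_SIM",
    "PMD_SIM",
]


@dataclass
class SimConfig:
    """Generative parameters for a single-chromosome synthetic methylome.

    ``mean_feature_cpgs`` / ``mean_gap_cpgs`` are the geometric mean run
    lengths (in CpG count) of planted features and of the background between
    them; ``coverage`` is the Poisson mean read depth per site.  When
    ``embedded_rate`` is positive, each in-feature site can open a short
    embedded run emitting from ``embedded`` — used for mosaic methylomes
    where hypo-methylated stretches sit inside hyper-methylated blocks (the
    embedded run still belongs to the planted feature).
    """

    n_cpgs: int = 10_000
    mean_gap: float = 100.0  # bp between adjacent CpGs (geometric, >= 2)
    coverage: float = 20.0  # Poisson mean depth
    background: BetaBinomialParams = field(
        default_factory=lambda: BetaBinomialParams(17.0, 3.0)  # mean 0.85
    )
    feature: BetaBinomialParams = field(
        default_factory=lambda: BetaBinomialParams(1.0, 19.0)  # mean 0.05
    )
    mean_feature_cpgs: float = 30.0
    mean_gap_cpgs: float = 270.0
    feature_name: str = "HMR"
    embedded: BetaBinomialParams | None = None
    embedded_rate: float = 0.0  # per-site probability of opening an embedded run
    mean_embedded_cpgs: float = 5.0
    conversion_failure: float = 0.0  # unmethylated molecules read out as C
    chrom: str = "chr1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cpgs < 0:
            raise ValueError("n_cpgs must be non-negative")
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")
        if self.mean_gap < 2:
            raise ValueError("mean_gap must be >= 2 (CpGs are two bases apart)")


@dataclass
class TruthSet:
    """Planted features per class plus per-site hidden-state labels.

    ``labels``: 0 = background, 1 = feature, 2 = embedded run inside a
    feature (labels 1 and 2 jointly form the planted feature intervals).
    """

    features: dict[str, list[GenomicFeature]]
    labels: np.ndarray


# Standard study conditions reused across tests and the acceptance script.
HMR_SIM = SimConfig()
HYPERMR_SIM = SimConfig(
    n_cpgs=3000,
    background=BetaBinomialParams(0.4, 19.6),  # mean 0.02: unmethylated background
    feature=BetaBinomialParams(18.0, 2.0),  # mean 0.90: hyper-methylated blocks
    mean_feature_cpgs=60.0,
    mean_gap_cpgs=60.0,
    feature_name="HyperMR",
    embedded=BetaBinomialParams(0.4, 19.6),
    embedded_rate=0.02,
    mean_embedded_cpgs=4.0,
)
PMD_SIM = SimConfig(
    n_cpgs=8000,
    mean_gap=50.0,
    background=BetaBinomialParams(17.0, 3.0),  # mean 0.85
    feature=BetaBinomialParams(9.0, 11.0),  # mean 0.45: partial methylation
    mean_feature_cpgs=400.0,  # ~20 kb domains at 50 bp spacing
    mean_gap_cpgs=400.0,
    feature_name="PMD",
)


def _geometric_lengths(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    p = min(1.0, 1.0 / max(mean, 1.0))
    return rng.geometric(p, size=size)


def _plant_states(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Hidden labels per CpG from alternating geometric runs (starts in background)."""
    n = config.n_cpgs
    labels = np.zeros(n, dtype=np.int8)
    i = 0
    in_feature = False
    while i < n:
        mean = config.mean_feature_cpgs if in_feature else config.mean_gap_cpgs
        run = int(_geometric_lengths(rng, mean, 1)[0])
        if in_feature:
            labels[i : i + run] = 1
        i += run
        in_feature = not in_feature
    if config.embedded is not None and config.embedded_rate > 0:
        j = 0
        while j < n:
            if labels[j] == 1 and rng.random() < config.embedded_rate:
                run = int(_geometric_lengths(rng, config.mean_embedded_cpgs, 1)[0])
                k = j
                while k < min(j + run, n) and labels[k] == 1:
                    labels[k] = 2
                    k += 1
                j = k
            else:
                j += 1
    return labels


def simulate_methylome(
    config: SimConfig, seed: int | None = None
) -> tuple[list[CytosineRecord], TruthSet]:
    """Generate sorted CpG-sym records and the planted truth.

    Deterministic given the seed (argument overrides ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_cpgs
    labels = _plant_states(config, rng)

    gaps = 1 + _geometric_lengths(rng, config.mean_gap - 1, n)  # >= 2
    positions = np.cumsum(gaps)

    t = rng.poisson(config.coverage, size=n)
    emissions = {
        0: config.background,
        1: config.feature,
        2: config.embedded if config.embedded is not None else config.feature,
    }
    p = np.empty(n)
    for lab, em in emissions.items():
        mask = labels == lab
        if mask.any():
            p[mask] = rng.beta(em.alpha, em.beta, size=int(mask.sum()))
    m = rng.binomial(t, p)
    if config.conversion_failure > 0:
        m = m + rng.binomial(t - m, config.conversion_failure)

    records = [
        CytosineRecord(config.chrom, int(positions[i]), "+", "CpG-sym", int(m[i]), int(t[i]))
        for i in range(n)
    ]

    features: list[GenomicFeature] = []
    in_feat = labels > 0
    i = 0
    while i < n:
        if in_feat[i]:
            j = i
            while j + 1 < n and in_feat[j + 1]:
                j += 1
            features.append(
                GenomicFeature(
                    config.chrom,
                    int(positions[i]),
                    int(positions[j]) + 1,
                    name=f"{config.feature_name}{len(features)}",
                    score=j - i + 1,
                )
            )
            i = j + 1
        else:
            i += 1
    return records, TruthSet({config.feature_name: features}, labels)


def simulate_methylome_pair(
    config: SimConfig,
    emissions_a: dict[int, BetaBinomialParams] | None = None,
    emissions_b: dict[int, BetaBinomialParams] | None = None,
    diff_windows: Sequence[tuple[int, int]] = (),
    diff_a: BetaBinomialParams | None = None,
    diff_b: BetaBinomialParams | None = None,
    seed: int | None = None,
) -> tuple[list[CytosineRecord], list[CytosineRecord], TruthSet]:
    """Two methylomes sharing CpG positions and hidden labels.

    The positions and per-site labels are drawn once from ``config``; each
    sample then draws coverage and counts independently, with its own
    label-to-emission mapping (``emissions_a`` / ``emissions_b`` override
    the config's background (0) / feature (1) / embedded (2) emissions per
    hidden label).  ``diff_windows`` plant additional differential blocks:
    half-open CpG-index intervals where sample A emits from ``diff_a`` and
    sample B from ``diff_b`` (defaults: the config background), regardless
    of the hidden label.  The planted windows appear in the truth under
    the "DIFF" class.  This is the differential-methylation test bed:
    shared planted HMRs with a partially methylated diff window yield a
    pure partial-methylation DMR invisible to HMR-based comparison.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_cpgs
    labels = _plant_states(config, rng)
    gaps = 1 + _geometric_lengths(rng, config.mean_gap - 1, n)
    positions = np.cumsum(gaps)

    base = {
        0: config.background,
        1: config.feature,
        2: config.embedded if config.embedded is not None else config.feature,
    }
    diff_mask = np.zeros(n, dtype=bool)
    for s, e in diff_windows:
        diff_mask[s:e] = True

    def draw(
        overrides: dict[int, BetaBinomialParams] | None,
        diff_em: BetaBinomialParams | None,
    ) -> list[CytosineRecord]:
        emissions = dict(base)
        if overrides:
            emissions.update(overrides)
        t = rng.poisson(config.coverage, size=n)
        p = np.empty(n)
        for lab, em in emissions.items():
            mask = labels == lab
            if mask.any():
                p[mask] = rng.beta(em.alpha, em.beta, size=int(mask.sum()))
        if diff_mask.any():
            em = diff_em if diff_em is not None else config.background
            p[diff_mask] = rng.beta(em.alpha, em.beta, size=int(diff_mask.sum()))
        m = rng.binomial(t, p)
        return [
            CytosineRecord(
                config.chrom, int(positions[i]), "+", "CpG-sym", int(m[i]), int(t[i])
            )
            for i in range(n)
        ]

    records_a = draw(emissions_a, diff_a)
    records_b = draw(emissions_b, diff_b)

    features: list[GenomicFeature] = []
    in_feat = labels > 0
    i = 0
    while i < n:
        if in_feat[i]:
            j = i
            while j + 1 < n and in_feat[j + 1]:
                j += 1
            features.append(
                GenomicFeature(
                    config.chrom,
                    int(positions[i]),
                    int(positions[j]) + 1,
                    name=f"{config.feature_name}{len(features)}",
                    score=j - i + 1,
                )
            )
            i = j + 1
        else:
            i += 1
    truth_features = {config.feature_name: features}
    if diff_windows:
        truth_features["DIFF"] = [
            GenomicFeature(
                config.chrom,
                int(positions[s]),
                int(positions[e - 1]) + 1,
                name=f"DIFF{i}",
                score=e - s,
            )
            for i, (s, e) in enumerate(diff_windows)
        ]
    return records_a, records_b, TruthSet(truth_features, labels)


# ---------------------------------------------------------------------------
# epireads


def simulate_epireads(
    n_cpgs: int,
    amr_windows: Sequence[tuple[int, int]] = (),
    reads_per_cpg: float = 20.0,
    read_len_cpgs: int = 4,
    allele_levels: tuple[float, float] = (0.9, 0.1),
    background_profile: float | np.ndarray = 0.85,
    chrom: str = "chr1",
    seed: int | None = None,
) -> tuple[list[Epiread], TruthSet]:
    """Generate epireads with planted allele-specific regions.

    ``amr_windows`` are half-open CpG-index intervals; inside them each read
    is assigned allele 1 or 2 with probability 1/2 and emits C at each CpG
    with that allele's level; outside, a single background profile (scalar
    or per-CpG array) is used.  Coordinates in the returned truth are CpG
    indices.
    """
    rng = np.random.default_rng(seed)
    bg = np.broadcast_to(np.asarray(background_profile, dtype=float), (n_cpgs,))
    amr_mask = np.zeros(n_cpgs, dtype=bool)
    for s, e in amr_windows:
        amr_mask[s:e] = True

    n_reads = int(round(n_cpgs * reads_per_cpg / read_len_cpgs))
    max_start = max(n_cpgs - read_len_cpgs, 0)
    starts = np.sort(rng.integers(0, max_start + 1, size=n_reads))
    alleles = rng.integers(0, 2, size=n_reads)

    epireads: list[Epiread] = []
    for start, allele in zip(starts, alleles):
        idx = np.arange(start, min(start + read_len_cpgs, n_cpgs))
        levels = np.where(amr_mask[idx], allele_levels[allele], bg[idx])
        calls = rng.random(len(idx)) < levels
        states = "".join("C" if c else "T" for c in calls)
        epireads.append(Epiread(chrom, int(start), states))

    features = [
        GenomicFeature(chrom, int(s), int(e), name=f"AMR{i}", score=e - s)
        for i, (s, e) in enumerate(amr_windows)
    ]
    labels = amr_mask.astype(np.int8)
    return epireads, TruthSet({"AMR": features}, labels)


# ---------------------------------------------------------------------------
# mapped reads


def simulate_duplicated_reads(
    n_fragments: int,
    dup_rate: float,
    seed: int | None = None,
    read_len: int = 50,
    chrom: str = "chr1",
    region_size: int = 1_000_000,
    library: str = "libA",
) -> tuple[list[MappedRead], int]:
    """Unique fragments each duplicated k >= 1 times (k-1 geometric).

    ``dup_rate`` in [0, 1) is the success parameter of the duplicate-count
    tail: expected duplicates per fragment = dup_rate / (1 - dup_rate);
    dup_rate = 0 produces no duplicates.  Returns (sorted reads, n_unique).
    """
    if not 0 <= dup_rate < 1:
        raise ValueError("dup_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(0, region_size - read_len, size=n_fragments))
    strands = rng.choice(["+", "-"], size=n_fragments)
    if dup_rate > 0:
        copies = rng.geometric(1 - dup_rate, size=n_fragments)
    else:
        copies = np.ones(n_fragments, dtype=int)
    reads: list[MappedRead] = []
    for i in range(n_fragments):
        bases = "".join(rng.choice(list("ACGT"), size=read_len))
        for k in range(int(copies[i])):
            reads.append(
                MappedRead(
                    chrom=chrom,
                    start=int(starts[i]),
                    end=int(starts[i]) + read_len,
                    strand=str(strands[i]),
                    name=f"frag{i}.{k}",
                    bases=bases,
                    quals=[40] * read_len,
                    library=library,
                )
            )
    reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    return reads, n_fragments


def simulate_bs_reads(
    reference: str,
    n_reads: int,
    read_len: int = 50,
    levels: float | dict[int, float] = 0.0,
    conversion_rate: float = 1.0,
    chrom: str = "chr1",
    seed: int | None = None,
) -> list[MappedRead]:
    """Bisulfite reads over an explicit reference sequence.

    At each reference C covered by a + strand read (G for - strand reads,
    reported on the + strand as G/A), the molecule is methylated with the
    site's level (scalar default or per-position dict); unmethylated
    cytosines convert to T with probability ``conversion_rate``.  All other
    positions copy the reference.  Useful for testing the counting and
    conversion-rate estimators against binomial expectations.
    """
    rng = np.random.default_rng(seed)
    ref = reference.upper()
    if read_len > len(ref):
        raise ValueError("read_len longer than reference")

    def level_at(p: int) -> float:
        if isinstance(levels, dict):
            return levels.get(p, 0.0)
        return float(levels)

    reads: list[MappedRead] = []
    starts = rng.integers(0, len(ref) - read_len + 1, size=n_reads)
    strands = rng.choice(["+", "-"], size=n_reads)
    for i in range(n_reads):
        s = int(starts[i])
        strand = str(strands[i])
        bases = list(ref[s : s + read_len])
        for j, base in enumerate(bases):
            p = s + j
            if strand == "+" and base == "C":
                if rng.random() < level_at(p):
                    bases[j] = "C"  # methylated: protected from conversion
                elif rng.random() < conversion_rate:
                    bases[j] = "T"
            elif strand == "-" and base == "G":
                if rng.random() < level_at(p):
                    bases[j] = "G"
                elif rng.random() < conversion_rate:
                    bases[j] = "A"
        reads.append(
            MappedRead(
                chrom=chrom,
                start=s,
                end=s + read_len,
                strand=strand,
                name=f"read{i}",
                bases="".join(bases),
                quals=[40] * read_len,
                library="libA",
            )
        )
    reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    return reads
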