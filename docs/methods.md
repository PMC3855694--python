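# Methods

This note records the models behind each caller, the defaults that
matter, the numerical choices, and what the synthetic-data tests do and
do not establish about real data.

## Per-cytosine levels

At each reference cytosine, reads on the informative strand contribute a
methylated (`C`, or `G` for − strand sites) or unmethylated (`T` / `A`)
observation; any other base is a mismatch and counts toward neither the
numerator nor the denominator.  The level estimate is `m / (m + u)` — an
unbiased estimate of the fraction of molecules carrying the mark, since
each read samples one molecule.  The two sites of a CpG dyad measure the
same methylation state, so `merge_symmetric_cpgs` pools them into one
`CpG-sym` record at the + strand C; pooling conserves both `Σm` and `Σt`
and is idempotent.  Per-site confidence intervals are Wilson score
intervals (default 95%), which behave sensibly at the `m = 0` and
`m = t` boundaries where Wald intervals collapse.

Region summaries report three statistics because they answer different
questions: the unweighted mean of site levels, the fraction of covered
sites above a methylated-call threshold (default level > 0.5), and the
coverage-weighted mean `Σm / Σt`, which is the maximum-likelihood pooled
estimate and the one used for region scores.  Mean coverage is reported
both over all cytosines and over CpG sites only, since both denominators
are in common use.

## HMR calling (two-state beta-binomial HMM)

Mammalian methylomes are modeled with a methylated background state and a
hypo-methylated state.  Emissions act on the counts, not the level
estimates: `m_i | s ~ BetaBinomial(t_i, α_s, β_s)`.  This absorbs both
binomial sampling noise (severe at low coverage) and biological
overdispersion; uncovered sites contribute likelihood 1 but are still
traversed by the chain, so a short uncovered stretch inside an HMR does
not split it.  Gaps larger than `desert_size` (default 1,000 bp) reset
the chain: beyond a coverage desert there is no information linking the
states, and treating the two sides as independent chains prevents a
desert from being "bridged" by one state.

Training is Baum–Welch with exact transition/initial M-steps and a
numerically maximized weighted beta-binomial emission M-step.  Emission
shapes are bounded to `[1e-3, 1e6]`: beyond ~1e6 the `betaln` difference
underlying the pmf loses all precision to cancellation, and an unbounded
optimizer will diverge into that regime on low-coverage data.  Each
emission update is guarded — if the optimizer's candidate has lower
expected log-likelihood than the current shapes, the current shapes are
kept — so the EM trace is non-decreasing (generalized EM).  Training
runs from two starts (method-of-moments fits on the level terciles, and
a canonical methylated/hypo prior) and keeps the better likelihood; the
tercile start degenerates at coverage ~1× where observed levels are only
0 or 1.  State 1 is relabeled after every M-step so it always carries
the lower emission mean.  Stopping: relative log-likelihood improvement
below `tol = 1e-4` or 100 iterations.

Decoding marks sites with posterior P(hypo) > 0.5 (ties to background,
the conservative choice) and merges maximal runs; Viterbi decoding is
available as an option.  Runs need `min_cpgs = 5` sites — single-site
"regions" are almost always noise.  A feature spans first CpG to one past
the last CpG, and its score column is its CpG count.

## HyperMR calling (three-state explicit-duration HMM)

Mosaic methylomes (plants, invertebrates, early germ cells) invert the
picture: an unmethylated background `B` with methylated blocks `H`, and
short unmethylated runs `E` embedded inside blocks.  The topology
`B ↔ H ↔ E` (E reachable only from H) encodes the embedding: merging
decoded H and E segments yields blocks that are not split by short
internal unmethylated runs.

Run lengths carry explicit durations, `d − 1 ~ NegativeBinomial(r, p)`
truncated at `l_max = 500` CpGs and renormalized; `r = 1` recovers the
geometric duration of an ordinary HMM.  The likelihood is
right-censored: the last segment of a chain must reach, but need not end
at, the last site, and carries the duration survival mass `P(d ≥ k)`.
This convention makes the geometric-duration model *exactly* equal to
the equivalent ordinary HMM (verified to 1e-6 in the tests and to
machine precision on short chains), which would not hold if the final
segment were forced to terminate.  Inference is the standard
semi-Markov forward–backward over (state, duration) with cumulative
emission sums, O(n · l_max) per state; posteriors come from
segment-start/segment-end event accumulation.  EM fits emissions as in
the HMR model, durations by numerically maximizing the expected
truncated-NB log-likelihood (censored segments are excluded from the
duration statistics — a small bias toward observed durations), and the
single free transition parameter (H → B vs H → E) in closed form; every
component is ascent-guarded.

## PMD calling (binned HMM + change-point refinement)

PMDs are tens-to-hundreds-of-kb domains of intermediate methylation, so
calling is hierarchical.  Counts of CpG-sym sites are pooled into 1 kb
tiling bins (empty bins retained) and a two-state beta-binomial HMM over
the pooled bin counts separates background from partially methylated
bins; the PMD state is initialized at mean 0.45 and identified as the
lower-mean state.  If the two trained means end up within 0.1 of each
other the genome has no partially methylated state and nothing is
called — on a homogeneous methylome the two states collapse onto one
level and decoding the collapsed pair is noise.

A domain boundary must lie inside the two bins straddling the coarse bin
edge, so refinement is a single change-point problem: scan every
inter-site breakpoint in that window and take the split maximizing the
two-segment binomial log-likelihood gain over the one-segment model.
Gains below 2 log units keep the bin-edge boundary (no real change
point); windows with fewer than two covered sites do the same.
Refinement is clamped so a boundary never leaves the two flanking bins.
Refined domains below `min_size = 10 kb` are dropped by default —
sub-10 kb "domains" are not PMDs in the accepted sense.  Evaluations of
segmentation fidelity in the tests disable this filter, because the
generator's geometric length distribution plants some genuinely short
domains that the filter would (correctly, per its contract) remove.

## AMR calling (read linkage)

`allelicmeth`: for each adjacent CpG pair, spanning reads form a 2×2
table of joint states (MM, MU, UM, UU) and a two-sided Fisher exact test
scores the association.  Only pairs with spanning coverage appear.

`amrfinder`: in a sliding window of `window_cpgs = 10` consecutive CpGs
(step 1, at least `min_reads = 10` overlapping reads), a one-allele
model — independent per-CpG levels with smoothed estimates
`(m + ½)/(t + 1)` — is compared against a two-allele model: an
equal-weight mixture of two per-CpG profiles into which reads are softly
assigned by EM (5 restarts: random splits plus a split on the first
covered CpG; smoothed profile updates; the monitored objective includes
the smoothing penalty and is non-decreasing).  The configuration with
both profiles equal reproduces the one-allele likelihood exactly, and is
always a candidate, so the two-allele log-likelihood never falls below
the one-allele one.  The statistic `2(ℓ₂ − ℓ₁)` is referred to a
chi-square with df = window size — deliberately generous (the true extra
dimensionality is smaller), making per-window p-values conservative —
then Benjamini–Hochberg at `q = 0.05` across windows, and overlapping
significant windows merge into AMRs.  A likelihood built instead on
hard read partitions with per-group integrated likelihoods was evaluated
and rejected: maximizing over partitions overfits so strongly that null
genomes are called allele-specific end to end.

## DMR calling

Per-CpG scores: with counts `(m_a, t_a)` and `(m_b, t_b)`, the score is
`P(p_A > p_B)` for `p_A ~ Beta(m_a, u_a + 1)`, `p_B ~ Beta(m_b + 1, u_b)`,
computed by an exact finite sum in log space.  Under exactly this prior
assignment the probability equals one minus the one-sided Fisher exact
p-value of the 2×2 table (Altham), so the score's upper tail is
calibrated: `P(score > 1 − a) ≤ a` under the null.  The lower tail is
*not* calibrated — the discrete tie mass piles there (two fully
methylated tied sites score exactly 0) — so evidence in the opposite
direction always uses the swapped score's upper tail.  Sites uncovered
in either sample are missing.

The fragment method evaluates the contiguous parts of the symmetric
difference of the two samples' HMR sets.  A fragment from sample A (A
has the HMR, i.e. A is hypo) is a DMR when at least `min_sig_cpgs = 5`
of its CpGs have swapped-score > 1 − 0.05; fragments with fewer than
`min_covered = 10` CpGs covered in both samples are dropped as
lack-of-data rather than called.  For cross-sample comparison the two
HMR sets should be produced with one set of trained parameters (the
`--params-in/--params-out` mechanism): with per-sample training, a
partially methylated block in one sample can drag that sample's hypo
state toward it and turn the block into a spurious "HMR".

The HMM method reduces each scored site to a significance category
(A-significant / B-significant / neither; each directional category has
null probability ≤ 0.05) and segments the category sequence with a
three-state HMM — no difference, over-abundance of A-significant sites,
over-abundance of B-significant sites — with categorical emissions and
closed-form Baum–Welch M-steps.  Decoded directional runs are DMRs when
they contain at least 10 matching significant CpGs; on split-half null
pairs, spurious runs carry at most ~7.  Because it works on per-site
scores rather than on HMR sets, this method also detects partial
differences (e.g. 0.8 vs 0.5) that create no HMR in either sample; the
fragment method, by design, cannot.

## Read preprocessing

Duplicates share (chromosome, start, end, strand) and one is kept
uniformly at random per library — reads from different libraries are
necessarily distinct molecules and never collapse.  Overlapping mates
have the overlap removed from the mate with the lower summed base
quality over the overlapped segment (ties clip mate 2; a mate entirely
inside the overlap is dropped), so no position is counted twice.  The
bisulfite conversion rate is `T / (T + C)` over read bases at control
cytosines known to be unmethylated (spike-ins, mitochondrial DNA), with
strand-appropriate complementation and an option to exclude CpG-context
controls against residual methylation.

## Synthetic data

The generator mirrors the segmentation models: CpG positions with
geometric gaps (mean 100 bp; 50 bp for the PMD configuration), hidden
labels from alternating geometric runs in CpG count, Poisson coverage,
and beta-binomial counts given the label.  Standard configurations:
background mean 0.85 (α+β = 20) with HMRs at mean 0.05, runs of 30/270
CpGs; mosaic background 0.02 with blocks at 0.90, runs 60/60 and short
embedded runs; PMD background 0.85 with domains at 0.45, runs 400/400
CpGs.  Epireads draw per-read allele assignments (probability ½ inside
planted AMR windows) and per-CpG Bernoulli states from the allele's
profile (0.9 vs 0.1 by default, background 0.85, 4 CpGs per read).
Paired methylomes share positions and labels and draw counts
independently, optionally with planted differential windows.

What the generator does not emulate: sequencing errors and mapping
artifacts, CpG-density structure (islands), non-CpG methylation,
per-cycle M-bias, length distributions of real features (real PMD and
HMR lengths are heavier-tailed than geometric), or correlated coverage.
Passing the planted-recovery tests therefore demonstrates correct
inference under the models' own assumptions — not performance on real
libraries, where mapping quality and coverage structure dominate.

## Problem sizes and runtime choices

Test and acceptance runs use 10,000 CpGs for HMR recovery, 50,000 for
HMM parameter recovery, 3,000 (with `l_max = 200`, 12 EM iterations) for
the explicit-duration model, 8,000 dense CpGs (~400 kb) for PMDs, 4,000
CpGs per point for the coverage sweep, and 250–400 CpGs at 20
reads/CpG for the AMR analyses — sizes at which every estimate in the
suite is stable across seeds while the whole suite stays fast.  Oracle
comparisons use chains of ≤ 12 sites (2ⁿ path enumeration) and the full
count grid `t ≤ 12` for the differential score.

## Known limitations

Single-sample callers only (no joint multi-sample training); two-sample
DMRs without biological-replicate variance modeling; no genotype-aware
phasing or parent-of-origin assignment for AMRs; SAM input is restricted
to ungapped alignments; no track-hub/bigWig output.  The explicit
duration family is negative binomial by construction — other families
would need a new M-step.
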