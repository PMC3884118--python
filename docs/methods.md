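# Methods

This note documents the models, parameter choices and numerical details
behind `isoprobe`, and what the synthetic-data tests do and do not
demonstrate about real array data.

## Exact matching as the alignment operating point

Probe-to-transcript assignment keeps only alignments with 100% identity
over the probe's complete 25-base length. At that operating point a
seeded local aligner and exact substring search are equivalent: a 25-mer
has such an alignment iff it occurs verbatim in the transcript. We
therefore index every N-free 25-mer of the reference (hash map of word →
occurrence list) and look probes up directly, which is simpler, faster and
bit-reproducible. Both strands are searched by default (`orientation both`),
mirroring a two-strand nucleotide search, because probe files in the wild
differ in whether probe sequences are sense or antisense to the transcript;
each hit records which orientation matched. A probe containing N can never
certify a perfect match and is reported `unmatched`.

Specificity is defined over distinct transcript accessions in the whole
reference set: a good probe hitting exactly one accession is
transcript-specific, even if it hits that accession at several positions
(flagged `multi_position` and kept — exclusion would silently discard
repeat-region probes, and a repeated match within one transcript does not
compromise transcript specificity). Versioned accessions are compared
verbatim; deduplicating superseded transcript versions is the caller's job.

## Cluster geometry

The MM partner of a PM probe is assumed at `(x, y+1)`, the standard 3′
array layout. `mm_offset=None` declares a PM-only platform, in which case
detection calls are unavailable and only the signal path runs. Probe pairs
whose MM cell would fall off the array edge (configurable `max_y`) are
dropped with a warning rather than guessed. The minimum-probes-per-cluster
threshold defaults to 1 so that no information is discarded silently;
analyses that feed wet-lab candidate selection use ≥ 6 pairs (below).

## Detection calls

Per cluster and hybridization the discrimination scores
`R_i = (PM_i − MM_i)/(PM_i + MM_i)` are tested against the discrimination
threshold τ with a one-sided Wilcoxon signed-rank test of `R − τ`
(alternative: median > 0). τ defaults to 0.015, the conventional default
for this detection algorithm, and is exposed in `CallThresholds`. Zeros
(`R_i = τ`) are dropped; tied absolute differences take mid-ranks. For
n ≤ 20 remaining scores the null distribution is enumerated exactly over
all 2^n sign assignments (subset-sum doubling, so the tie structure is
honored exactly); above n = 20 the normal approximation with continuity
correction and tie-corrected variance is used. The switch point is far
above typical cluster sizes (≤ 16 pairs on 3′ arrays), so real calls are
effectively always exact. If every score equals τ the test degenerates and
p = 1 is returned.

Calls: present if p ≤ 0.05, absent if p ≥ 0.065, marginal strictly in
between. Both cutoffs are inclusive on their own side, so p = 0.05 is
present and p = 0.065 is absent.

Two deliberate divergences from the full MAS5 signal pipeline: we do not
compute Tukey-biweight signal values (the downstream decision logic uses
only the calls), and saturated-MM special-casing is omitted (synthetic and
modern data do not saturate).

## Expression signals

The signal path is quantile normalization of the clustered PM cells,
log2, and per-cluster two-way median polish (row sweeps first; stop when
the largest absolute change in a sweep is < 0.01 or after 10 sweeps). The
reported signal is overall effect + hybridization effect; a 1-probe
cluster degenerates to that probe's log2 values. Quantile normalization
maps each column onto the across-column mean of order statistics;
fractional (tied) ranks interpolate between adjacent order statistics, so
it is idempotent and rank-preserving. Convolution background correction
(exponential signal + normal noise, parameters from the density mode) is
available behind `background="rma-conv"` but off by default: the default
path is deterministic, parameter-free and sufficient for the detection and
consensus logic, which depends only on calls.

## Consensus, percentage detection, reliability

A transcript's consensus across hybridizations is a majority vote between
present and absent calls; marginal calls never vote but do count in the
percentage-detection denominator (`pct = 100·max(n_present, n_absent)/n`).
This keeps the canonical 4-present-1-absent → 80% example intact while
penalizing marginal-heavy profiles; the denominator rule is configurable
(`marginal_in_denominator=False`) because other tools differ here.
Reliability ranks bin consistency into deciles anchored at the top: rank 1
for ≥ 90%, rank r for `[100−10r, 100−10(r−1))`, rank 10 absorbing
everything below 10%.

## Differential analysis

Regulation: per transcript, group means of log2 signals and a two-sided
t-test; Welch (unequal variance) by default as the safer choice for small,
possibly heteroscedastic groups, with the pooled-variance variant
available. Fold change is the log2 mean difference (group A − group B),
also displayed as a linear ratio `2^|Δ|`. Significance is the plain
p ≤ 0.05 rule with no multiple-testing correction, matching the decision
rule this pipeline family uses; Benjamini–Hochberg q-values are available
as an optional extra (`benjamini_hochberg`) but do not affect statuses.
Zero variance in both groups with equal means returns p = 1. Detection:
a transcript is differentially detected iff one group's consensus is
transcribed and the other's not-detected; no-call in either group reports
the pair unflagged.

## Candidate selection and concordance

Candidate selection for wet-lab verification retains transcripts whose
gene (a) has ≥ 2 transcripts and (b) is externally called transcribed at
reliability rank ≤ 5, where (c) one isoform is transcribed and another
not-detected, both at rank ≤ 3, and (d) the transcript's cluster has ≥ 6
probe pairs. The external gene-level calls are an input table, not
recomputed.

Concordance compares a transcript's per-hybridization call profile (the
`T-ND-M` triple, e.g. `31-0-0`) with per-sample observed statuses.
"Uniform" means zero dissenting calls of any kind, including marginal. A
transcript is *complete agreement* if its profile is uniform and every
sample matches the majority status, *contradiction* if uniform and every
sample mismatches, *partial* otherwise (all non-uniform profiles land
here). Summary percentages are rounded to the nearest integer; pair-level
agreement counts each (transcript, sample) pair once and is also reported
restricted to uniform profiles and to uniformly transcribed profiles.

## Synthetic data model

The generator emulates the pipeline's inputs with exact ground truth, not
realism:

- **Transcriptome.** Each gene draws its isoform count from (60% one, 30%
  two, 10% three) and a total length from 300–1200 nt. Multi-isoform genes
  share a constitutive 5′ block; every transcript ends in a unique block
  (150 nt by default, ≥ 50 enforced) whose 25-mers are rejection-sampled
  to occur nowhere else, then verified by a global k-mer count — so
  "specific" probes are transcript-specific with certainty, not with high
  probability.
- **Probes.** 11 per transcript (typical 3′-array probe-set size); for
  multi-isoform genes 25% are drawn from the constitutive block (matching
  all isoforms), the rest from unique blocks. 20 decoys are transcript
  25-mers with 1–2 substitutions, verified non-matching on both strands.
  PM cells occupy even grid rows so each MM partner cell is free.
- **Intensities.** Per probe pair and hybridization one background draw
  `b ~ logN(log 100, 0.3)` is shared by PM and MM; an expressed transcript
  adds signal `a·φ` to PM and `crosstalk·a·φ` to MM, with abundance
  `a = 500·logN(0, 0.25)` per transcript × hybridization, probe affinity
  `φ ~ logN(0, 0.3)`, crosstalk 0.3, and independent multiplicative noise
  `logN(0, 0.15)` on every cell. Expression flags are drawn once per
  transcript (probability 0.5) and held across hybridizations, so
  consensus truth is well defined. With crosstalk and noise at zero the
  model degenerates exactly: absent transcripts give PM = MM, hence scores
  of 0 and p = 1.

These parameters were chosen once as plausible raw-fluorescence-scale
values giving roughly 2–5× PM/MM separation for expressed transcripts —
comparable to a clearly detected probe set on a real chip — and are not
fitted to any dataset. Default study size is 30 genes × 6 hybridizations
(~50 transcripts, ~500 probe pairs), which exercises every code path in
seconds while leaving detection genuinely noisy for absent transcripts
(~2–4% false presents per hybridization, as on real arrays).

What the synthetic tests therefore show: the pipeline's decision logic
recovers known truth under its own assumptions (independent probes,
shared-background PM/MM pairs, no cross-hybridization beyond the MM
crosstalk term, no spatial artifacts, no batch effects). What they do not
show: robustness to probe thermodynamic variation, saturation, spatial
defects, or misannotated references — real-data properties the model
deliberately omits.

## Degenerate inputs and tie-breaks

- Transcripts shorter than 25 nt are skipped with a warning and counted in
  the index's skip report.
- Duplicate (probe, accession) hits from multi-position probes contribute
  one cluster pair (first occurrence by position).
- `consensus_call` on an empty vector, `detection_p` on an empty score
  list, and mixed record kinds in one results file are hard errors.
- All text output prints 6 significant digits; p-values in scientific
  notation. Written-then-read equality is exact for integers and strings
  and to 6 significant digits for reals.

## Known limitations

- Exact matching cannot emulate alignments below the 100%/100% operating
  point; near-miss probes that a permissive aligner would rescue are
  `unmatched` here, by design.
- The Wilcoxon variant and τ used by any particular legacy implementation
  may differ; ours is documented above rather than claimed bit-equal.
- Binary chip formats (.CEL/CHP/CDF) are out of scope; intensities enter
  through the cells × hybridizations TSV, which must contain both PM and
  MM cells when detection calls are wanted.
- The acceptance script's cohort reconstruction reproduces published
  category arithmetic from its printed counts; the per-sample split of
  partially agreeing transcripts is not public, so the overall pair-level
  agreement over all profiles is reported but not checked against a
  reference value.
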