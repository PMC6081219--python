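# Methods

`ampliconcnv` detects germline copy-number variants from the per-amplicon
read-depth matrix of a multiplex-PCR (amplicon) targeted sequencing run.
Because every read of an amplicon library comes from one of a fixed set of
PCR products, the amplicon-level depth-of-coverage table emitted by the
sequencer's coverage analysis is a sufficient input — no base-level pileup
or BAM processing is needed.

## Normalization model

For sample *s*, let *x₁…x_m* be the raw depths of the *m* amplicons of
primer pool 1 and *y₁…y_n* those of pool 2 (any number of pools is
supported; each amplicon belongs to exactly one pool):

1. **Pool means** — x̄ₛ = (x₁+…+x_m)/m per (sample, pool). Amplicon
   libraries mix two separately amplified primer pools, and the mixing
   ratio varies between libraries; each pool therefore needs its own
   per-sample depth scale.
2. **Relative depths** — rᵢₛ = xᵢₛ / x̄ₛ. This cancels library size and
   pool imbalance; relative depths are comparable across samples.
3. **Batch reference** — r̄ᵢ = (rᵢ₁+…+rᵢ_p)/p over the *p* samples of the
   batch (all samples sequenced in one run; the method is calibrated on
   45-sample batches but *p* is free). This is the population-based step:
   each amplicon's amplification efficiency (primer kinetics, GC content,
   product length) is highly reproducible across samples, so the batch
   average is a per-amplicon efficiency reference.
4. **Normalized relative depth** — tᵢₛ = 2 · rᵢₛ / r̄ᵢ, a copy-dosage
   scale on which a diploid locus averages exactly 2 across the batch (by
   construction), a heterozygous deletion sits near 1, a one-copy gain
   near 3.

**Outlier removal.** Amplicons with batch-mean relative depth r̄ᵢ ≤ 0.1
(parameter `outlier_threshold`) are masked from all statistics and plots:
ratios against a near-zero reference are dominated by sampling noise. The
boundary is inclusive (exactly 0.1 is removed).

**Undefined values** (zero pool mean, zero reference) propagate as NaN,
never as zeros — an observed zero is a meaningful homozygous-deletion
signal and must not be conflated with "could not be computed".

**Sex chromosomes** are deliberately *not* normalized separately. In a
mixed-sex batch the chrX reference corresponds to ~1.5 copies, so males
show ≈ 2·(1/1.5) = 1.3 and females ≈ 2·(2/1.5) = 2.7 on chrX — sex is
readable directly from the profile. The exact values carry a small
correction: male chrX depths also shrink the male pool means. With *f* the
chrX share of a pool's depth mass, the noiseless values are 2/(1.5 − f/2)
for males and (4 − 2f)/(1.5 − f/2) for females; the familiar 1.3/2.7 are
the f → 0 limits and hold to one decimal for panels whose chrX share is
small (≲4%), as in the 63-gene/2,064-amplicon design the defaults mirror.
An optional `sex_aware` mode computes the reference within sex groups
(flattening chrX to 2); `leave_one_out` excludes the query sample from its
own reference. Both are off by default to match the plain batch-average
behavior.

## Detection

Retained amplicons are sorted in genomic order (chr1–chr22, chrX, chrY,
then others lexicographically; position within chromosome).

- **Smoothing**: centered moving mean, window 5 (odd, configurable),
  restricted within each (chromosome, gene) group — targeted panels have
  megabase gaps between genes. At group edges the window truncates to the
  available in-gene amplicons.
- **±1 SD candidates**: per sample, amplicons whose normalized depth
  deviates from the sample mean by more than `sd_multiplier` (default 1)
  population standard deviations (ddof = 0; configurable).
- **Windowed t-test**: every run of 5 contiguous retained amplicons within
  a chromosome is tested against the sample's remaining retained
  amplicons; default is a two-sample Welch test with the window excluded
  from the background (excluding it keeps large events from contaminating
  the null; an include-all mode and a one-sample mode are provided). The
  two-sided p-value is assigned to the window's center amplicon. No
  multiple-testing correction by default — the p-values aid inspection —
  with optional Benjamini–Hochberg per sample. Zero variance in both
  groups takes the limit convention p = 1 if the means agree, else 0.
- **Copy-state bands**: smoothed dosage is cut at the midpoints of the
  integer copy levels: [0, 0.5) → 0, [0.5, 1.5) → 1, [1.5, 2.5] → 2 (no
  call), (2.5, 3.5] → 3, above 3.5 → "4 or more".

### Segment calling

Calling replaces the manual curation of the depth plots with an explicit,
reproducible rule:

1. **Candidate runs** are maximal same-band stretches of the *smoothed*
   profile per chromosome; same-state runs separated by ≤ `merge_gap`
   (default 2 = half the smoothing window) amplicons are bridged, since
   blips shorter than the half-window are smoothing artifacts.
2. **Boundary refinement**: smoothing blurs event edges by up to half a
   window, so each run boundary is re-placed on the *unsmoothed* values by
   a local least-squares changepoint fit of a step profile within ±5
   amplicons of the smoothed edge. The step levels are estimated
   empirically (median of the run vs the sample's global median) because a
   carrier's own event shifts its pool means and the batch reference — a
   trisomy carrier's "3-copy" level is observed near 2.8 and its diploid
   level near 1.9. Squared errors are weighted by 1/level², matching
   count noise whose standard deviation grows with dosage. Outward search
   stops at amplicons whose own band contradicts the run (opposite side of
   diploid; also the zero band when extending one-copy runs, since a zero
   depth is a near-noiseless signal of a distinct homozygous event).
3. **Aneuploidy snap**: a run spanning ≥ 2 genes and ≥ 80% of a
   chromosome's amplicons that ends within `merge_gap` of a chromosome
   terminal is extended to the terminal — the multi-gene whole-chromosome
   pattern is read as aneuploidy, exactly as a curator reads a trisomy.
4. Runs of ≥ `min_run` (default 3) amplicons become calls, reporting
   genomic extent (1-based inclusive coordinates for reporting; BED inputs
   stay 0-based half-open in memory), copy state, mean unsmoothed
   normalized depth, whether ≥ half the amplicons carry the SD flag, and
   the minimum window p-value in the run.

Known limitation: partially overlapping smoothing windows at the edges of
deep (homozygous) deletions can produce short adjacent intermediate-state
runs; boundary refinement trims these below `min_run` in practice, but
they can surface as short single-copy calls flanking a homozygous call in
noisy data. Breakpoints are resolved at amplicon granularity only, and no
Hidden-Markov copy-number model is attempted — the calling rule is a
transparent surrogate for visual curation, not a probabilistic segmenter.

### Batch QC

Per sample, the scaled median absolute deviation (MAD, normal-consistent)
of the retained normalized depths; samples with MAD > `qc_threshold`
(default 0.5) are unanalyzable — the practical failure mode is a scattered
profile from a large pool-1/pool-2 library imbalance, so the raw pool-mean
ratio is reported alongside. On clean simulated batches at default noise
the MAD sits near 0.3; the threshold 0.5 separates those from
overdispersed/imbalanced batches (MAD ≳ 0.8) with a wide margin.

## Synthetic batches

The simulator generates coverage matrices with known truth. Expected depth
of amplicon *a* in sample *s*:

    E[x_as] = depth_s · eff_a · poolfactor_{s, pool(a)} · dosage_as / 2

- `eff_a`: log-normal (σ = 0.5) per-amplicon amplification efficiency —
  the dominant source of between-amplicon spread in multiplex PCR.
- `depth_s`: mean depth 500 reads with log-normal (σ = 0.2) sample scale.
- `poolfactor`: log-normal (σ = 0.15) per-(sample, pool) mixing imbalance,
  plus an optional systematic pool-2 factor.
- `dosage`: 2 on autosomes, 1/2 on chrX for males/females, the event's
  copy number inside injected events (gene- or chromosome-scoped ranges).
- Counts: negative binomial with dispersion k = 50, giving a coefficient
  of variation ≈ 15% at depth 500 (a realistic mid-range for amplicon
  panels); Poisson and an exact noiseless mode are available. The
  noiseless mode emits the exact expected depths as floats so closed-form
  checks hold to machine precision.

Default panel: 20 genes × 15 amplicons, two interleaved pools, two genes
on a chr21 stand-in (trisomy control) and two on chrX; one autosomal gene
is named STRC on chr15. The simulator reproduces — rather than hides — the
reference-bias of the literal equations: a carrier contributes to the
batch reference, so its normalized dosage is pulled slightly toward 2, with
the bias shrinking as 1/batch-size (covered by a test). What the simulator
does **not** emulate: GC-dependent efficiency drift between samples,
segmental-duplication cross-mapping (the real STRC pitfall),
run-to-run batch effects, and mosaicism — so passing tests demonstrate
correctness of the arithmetic and the calling logic under the stated noise
model, not robustness to every artifact of real libraries.

## Measured detection performance

At the default study conditions (45-sample batches, NB noise, CV ≈ 15% at
depth 500), over 100 simulated replicates per seed block, `call_segments`
recovers (correct copy state, both boundaries within ±1 amplicon):
10-amplicon heterozygous losses in ≈ 98–100% of replicates, homozygous
losses in ≈ 100%, whole-chromosome trisomies in ≈ 98–99%, and 10-amplicon
one-copy gains in ≈ 83–93%. The gain figure is at the statistical ceiling,
not an implementation gap: a Monte Carlo of the Bayes-optimal changepoint
(true levels and variances known) under the same conditions places one
boundary within ±1 amplicon with probability 0.954, so both boundaries of
a gain are within ±1 at most ~91% of the time. Gains are simply the
hardest state to delimit: the 2→3 step is one noise-unit smaller relative
to its variance than the 2→1 step.

## Numerical conventions

- Population (ddof = 0) SD for candidate flagging; sample variance inside
  the t-tests.
- Copy-state band boundaries: values exactly at 1.5/2.5 are diploid;
  exactly 0.5 is state 1; exactly 3.5 is state 3.
- Normalized matrices are serialized with 6 decimals and round-trip to
  1e-6; undefined values serialize as `NA`.
- All randomness flows through one `numpy` Generator seeded from the
  config; identical seeds give byte-identical simulated batches.
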