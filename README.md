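# ampliconcnv

Germline copy-number variant (CNV) detection and visualization for
multiplex-PCR amplicon panels (Ion AmpliSeq-style targeted sequencing).

Hybridization-capture CNV tools don't transfer to amplicon data: reads are
single-ended PCR products, each target is covered by essentially one
amplicon, and split-read/paired-end signals don't exist. What amplicon data
do offer is a highly reproducible per-amplicon depth of coverage.
`ampliconcnv` turns the barcode/amplicon coverage matrix of a sequencing
run into a copy-dosage profile per sample, flags candidate CNVs, and draws
the per-gene depth plots used to curate them. It is aimed at diagnostic
panels (the defaults mirror a 63-gene hearing-loss design where *STRC*
deletions are the most common finding), but any amplicon panel with
primer-pool annotations works.

## Method

With `x_i` the raw depth of amplicon *i* in a sample and pools normalized
separately (m amplicons in pool 1, etc.):

    x̄    = (x₁ + … + x_m)/m          pool-mean depth per sample
    r_i  = x_i / x̄                    relative depth (library/pool effects cancel)
    r̄_i  = (r_i1 + … + r_ip)/p        batch reference over the run's p samples
    t_iq = 2 · r_iq / r̄_i             normalized relative depth (diploid ≈ 2)

Amplicons with r̄ᵢ ≤ 0.1 are masked as unreliable. Downstream, per sample:
5-amplicon moving-average smoothing within genes, ±1 SD candidate
flagging, a sliding 5-amplicon Welch t-test against the rest of the
profile, and explicit copy-state calls (bands cut at 0.5/1.5/2.5/3.5 with
changepoint-refined boundaries). A per-sample QC statistic (scaled MAD of
the profile) flags unanalyzable libraries, typically those with a large
pool-1/pool-2 imbalance. A bundled simulator generates batches with known
truth (amplification-efficiency spread, pool imbalance, count noise,
CNV/trisomy/sex-dosage events) and backs the test suite. See
`docs/methods.md` for the full model and its limitations.

## Worked example

Detect *STRC* losses injected into a simulated 45-sample batch
(`examples/02_detect_strc_loss.py`):

```sh
python examples/02_detect_strc_loss.py
```

```
injected truth:
sample_id gene chrom first_amplicon last_amplicon  n_amplicons  copy_number
     S005 STRC chr15  AMPL_STRC_001 AMPL_STRC_015           15            1
     S010 STRC chr15  AMPL_STRC_001 AMPL_STRC_015           15            0

STRC calls (copy_state 1 = one-copy loss, 0 = homozygous loss):
sample_id gene first_amplicon last_amplicon  copy_state  mean_norm_depth  sd_flag     t_p_value
     S005 STRC  AMPL_STRC_001 AMPL_STRC_015           1         1.132262     True  1.609160e-06
     S010 STRC  AMPL_STRC_001 AMPL_STRC_015           0         0.000000     True 1.157828e-188
```

Both events are recovered over their exact amplicon ranges: the one-copy
carrier's mean normalized depth is ≈ 1 (one of two copies left, slightly
above 1 because the carrier itself sits in the batch reference) and the
homozygous deletion is ≈ 0. `copy_state` is the called integer copy
number, `sd_flag` marks runs of ±1 SD outliers, and `t_p_value` is the
smallest sliding-window Welch p-value in the run.

Sex dosage and a trisomy stand-in
(`examples/03_trisomy_and_sex_dosage.py`) print, for a noiseless
balanced-sex batch:

```
chrX normalized depth, male S002:   1.384  (~4/3, prints as 1.3)
chrX normalized depth, female S001: 2.622  (~8/3, prints as 2.7)
chr21 normalized depth, trisomy carrier S003: 2.738  (~3; ...)
```

chrX is normalized against the mixed-sex batch average (~1.5 copies), so
male ≈ 2·(1/1.5) and female ≈ 2·(2/1.5) — sample sex is readable straight
off the profile. The remaining examples cover normalization invariants
(`01`), batch QC (`04`) and the blue/red profile figures (`05`).

## Command line

```sh
ampliconcnv simulate --out batch --seed 42          # synthetic batch + truth
ampliconcnv call --coverage batch/coverage.tsv \
    --bed batch/design.bed --meta batch/samples.tsv \
    --out results --plot per_gene                    # normalize, call, QC, plots
ampliconcnv plot --coverage batch/coverage.tsv \
    --bed batch/design.bed --sample S003 --out figs
```

Inputs are the tab-separated coverage matrix (either `amplicon_id …` or
`Gene/Target …` header dialect) and the designer's BED with a
`Pool=<int>` attribute per amplicon.

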