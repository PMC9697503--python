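# Methods

This note documents the models and procedures implemented in `phagedyn`,
the parameters that matter, the design choices that were genuinely open,
and the limits of what the synthetic benchmarks demonstrate.

## Data model

Samples are identified by `(time_min, replicate)`; time 0 is the
uninfected culture. Three tables flow through the pipeline: a gene
annotation (entity host/phage, length in nt, biotype, display name), an
integer count matrix (featureCounts layout), and real-valued abundance
matrices tagged with a unit (TPM, LFQ, or a derived per-gene scaling).
LFQ "not detected" is a first-class state: it is held as NaN, written to
TSV as `NA`, and coerced from the `0` that MaxQuant writes. It is
treated as 0 wherever abundances are summed or averaged (detection-limit
censoring) but a time point at which *all* replicates are undetected
stays undetected.

## Preprocessing

Order of operations for RNA-seq: **rRNA removal → TPM → low-count
filter**. rRNA genes are removed from the raw counts because rRNA was
depleted before library preparation; leaving them in would let a
residual, variable rRNA share distort the relative scale. The low-count
filter (default: mean raw count < 1.5 across all samples) is computed on
the *raw* counts but applied to the TPM matrix, i.e. surviving genes
keep the TPM values computed before filtering. Per-gene scalings
(z-score with population SD, fraction-of-max, percent-of-baseline)
operate on replicate-averaged matrices. The population (n) standard
deviation is used for z-scores so that a two-point profile maps to ±1;
constant profiles map to all zeros rather than NaN.

Entity fractions ("takeover curve") divide the summed abundance of each
entity by the total per sample. By default fractions are computed per
replicate and then averaged; computing them on the replicate-averaged
matrix is available as an option and differs only at third-decimal
level for balanced designs.

## Temporal classification

Onset = first sampled time with abundance ≥ `onset_fraction` (default
0.10) of the gene's maximum over the course. Classes: onset <
`early_end` → early; < `late_start` → middle; otherwise late. The
boundary mapping is deliberately half-open (`<` at `early_end`, `≥` at
`late_start`): with RNA boundaries (4, 7) an onset exactly at 4 min is
*middle* and at 7 min is *late*, which is the only mapping consistent
with the canonical worked examples of middle-promoter targets (onset
t4) and virion genes (onset t7). Onsets are assigned on the discrete
sampled grid; no interpolation or model-based change-point detection is
attempted. Genes with an all-zero profile are `unexpressed` and excluded
from peak tallies; genes below a minimal mean abundance (default 1 TPM
on the RNA layer, 0 on the LFQ layer, where intensities are already
censored at the detection limit) are excluded before classification.
Replicate averaging precedes onset detection; there is no per-replicate
voting.

Because classification depends only on profile shape, it is invariant
under positive rescaling; and decreasing any pre-onset value can only
move an onset later, never earlier. Both properties are tested.

## Host dynamics

The stability screen flags host genes with mean TPM ≥ 10 (mean over the
replicate-averaged time points) and a final-time/t0 TPM ratio ≥ 0.8.
The ratio is a plain ratio of replicate-averaged values, not a
regression slope, matching how such curves are normally plotted
(percent of the uninfected sample). Genes with zero baseline have an
undefined ratio and are never stable.

Host-proteome stability is summarized per protein as
m_p = max_t |log2(LFQ(t)/LFQ(0))| over the times at which the protein is
detected, with the cohort median and the fraction with m_p ≤ 1
(within two-fold) reported. Proteins undetected at t0 are excluded. The
targeted `abundance_ratio` statistic is the ratio of time-averaged LFQ
values of two proteins (undetected = 0 in the average), e.g. for
comparing a phage protease inhibitor with its host protease target.

## Integration

RNA and protein classifications are joined through a one-to-one
identifier map (the map is a required user input for real data, since
locus tags and protein accessions are harmonized differently in every
annotation pair). Genes classified on only one layer are excluded from
overlap counts but reported through the module logger. The class
overlap is rendered as the full 3×3 contingency table — strictly more
informative than pairwise Venn diagrams. "Decoupled" defaults to
early transcript + late protein; the class pair is configurable.

## Synthetic-data generator

The generator plants, in relative (TPM-like) abundance space:

* host mRNA/ncRNA: constant until `host_decay_delay_min` (default 1),
  then exponential decay at per-gene rates drawn around
  `host_decay_rate_per_min` (default 0.2/min, log-normal spread 0.25);
* stable host ncRNAs (default 4 of 1000 host genes): constant
  abundance, with baselines calibrated (see below) — these end up at
  several 10^4 TPM, matching the hyper-abundant character of real stable
  transcripts such as tmRNA;
* host tRNAs: a modest rise (×1.3) at the first sampled time, then
  decay;
* rRNA: a constant, small share of reads (default 0.5%), removed by the
  pipeline before TPM;
* phage genes in early/middle/late waves (default proportions
  0.78/0.08/0.14) with onset values ≥ 50% of the gene's maximum so that
  onsets are unambiguous; half of the early genes peak mid-infection
  and decline, the other half rise monotonically.

TPM is compositional, so a gene's *measured* trajectory depends on the
total abundance at each time. The generator pins the rRNA-free total:
once host decay has begun, the aggregate phage abundance is set to
exactly the mass the host has lost (before that, the phage holds a
small configured toehold, default 15% of the pre-infection total). Two
consequences: (i) planted exponential decays reappear as the same
exponentials in percent-of-baseline TPM curves, mirroring the roughly
constant total-RNA yields of real infection time courses; and (ii) the
final phage share of the transcriptome equals `takeover_final_fraction`
(default 0.83) exactly in expectation — the stable-RNA baselines are
solved from that constraint, which also makes the takeover curve
monotone.

Counts are drawn per sample as negative binomial (default dispersion
0.1, i.e. variance m + 0.1 m²) around `library_size` (default 2×10⁶)
times the gene's expected read share (abundance × length). `poisson`
and `none` (rounded expectation) noise modes exist for controls.

The proteome layer plants a constant host proteome (log-normal
baselines, median 5×10⁷) with multiplicative log-normal noise (default
sd 0.1 in ln-space), and phage proteins that are zero before a planted
onset and then ramp from 45% of their plateau to the plateau at the
final time. Intensities below `lfq_detection_limit` (default 2×10⁵) are
censored to not-detected. 60% of host-coding genes and 85% of phage
genes yield detected proteins; undetected phage proteins are drawn
preferentially from early transcripts, as observed in real data sets.
Protein classes follow the realized RNA classes except for a planted
*decoupled* subset (default 30% of the detected phage cohort:
early transcript, late protein); the total phage LFQ share at the final
time is calibrated to `lfq_final_phage_fraction` (default 0.14).

**Ground-truth labels** (onset, peak, class) are computed from the
exact noise-free expectation curves with an independent in-module copy
of the onset rule — not with the pipeline's classifier — so recovery
tests compare two implementations. With the default shape margins the
realized labels coincide with the intended class assignment for every
gene (asserted in tests).

All randomness derives from one integer seed through per-table
substreams (`(seed, crc32(table))`), making scenario files byte-stable.

## What the benchmarks do and do not show

The default scenario (1000 host + 500 phage genes, triplicates, the
sampling grids above) runs the full dual-omics pipeline in seconds on
one CPU; the acceptance script's ten-seed takeover average completes in
well under a minute. Passing tests demonstrate correct bookkeeping and
faithful recovery of dynamics *of the planted form*: smooth mean
curves, gene-independent negative-binomial/log-normal noise, no batch
or replicate effects, no mapping ambiguity, no isoform structure, and a
one-to-one gene–protein map. Real data violate all of these to some
degree; in particular the classifier's accuracy near phase boundaries
depends on how sharply real onsets rise, and the stability screen
inherits any compositional drift that real library preparation
introduces. The generator's class proportions and takeover endpoint are
realistic for a virulent T4-like phage but are not fitted to any
particular data set.

## Known limitations

* No between-sample normalization beyond TPM (no TMM/median-of-ratios)
  and no LFQ imputation — by design, since the downstream statistics
  are ratio- or shape-based.
* Differential-expression testing, COG/functional enrichment and
  replicate-QC ordinations are out of scope; dedicated tools exist.
* Onset detection has sampling-grid resolution; genes switching on
  between samples are assigned the next sampled time.
* `protein_stability_summary` skips times where a protein drops out of
  detection rather than treating them as infinite fold changes.
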