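# phagedyn

Time-resolved **dual-omics analysis of phage infection**: a tested Python
pipeline for gene-level RNA-seq count tables and label-free proteomics
(LFQ) tables sampled along an infection time course of a lytic phage
(e.g. T4) and its bacterial host (e.g. *E. coli*).

It is aimed at researchers who have featureCounts-style count matrices,
GFF3 annotations for both genomes, and MaxQuant `proteinGroups`-style
LFQ tables, and want to answer the standard questions of such
experiments:

* How quickly does the phage take over the transcriptome?
  (entity-resolved TPM fractions over time)
* Which phage genes are **early / middle / late**, on the RNA and on the
  protein layer?
* Which host transcripts survive the global host-mRNA degradation?
* Which genes are **temporally decoupled** — transcribed early but
  translated late — pointing at post-transcriptional regulation?

## The statistics at the core

**TPM normalization.** For gene *g* with length *L_g* (nt) and count
*c_g* in one sample, the rate is *r_g = c_g / (L_g/1000)* and

&nbsp;&nbsp;&nbsp;&nbsp;TPM_g = r_g / Σ_h r_h × 10⁶,

so each sample sums to 10⁶ and is invariant to sequencing depth.
rRNA genes (depleted before sequencing) are removed first; genes with a
mean raw count below 1.5 across all samples are removed from the TPM
matrix afterwards.

**Onset-based temporal classification.** A gene's onset is the first
sampled time at which its replicate-averaged abundance reaches ≥ 10% of
its maximum over the course (LFQ not-detected = 0). With phase
boundaries *(e, l)* the class is *early* if onset < *e*, *middle* if
*e* ≤ onset < *l*, *late* if onset ≥ *l*. The conventional boundaries
are (4, 7) min for the transcriptome and (5, 8) min for the proteome.

**Host stability screen.** A host transcript is *stable* when its mean
TPM over the time course is ≥ 10 and its TPM at the final time is
≥ 80% of its value in the uninfected sample.

**Integration.** RNA and protein classifications are joined through an
identifier map; the class overlap is reported as the full 3×3
contingency table, and early-RNA/late-protein genes are flagged as
decoupled.

A synthetic-data generator (`phagedyn.synthetic_data`) plants all of
these dynamics — delayed exponential host-mRNA decay, a small set of
hyper-abundant stable non-coding RNAs, rising-then-decaying tRNAs,
class-structured phage waves, a monotone takeover curve, a stable host
proteome, cumulatively appearing phage proteins — with a per-gene ground
truth, so every stage is testable end to end without any downloads.

## Worked example

```python
from phagedyn import (SimulationConfig, simulate_scenario, preprocess_counts,
                      mean_over_replicates, entity_fractions, classify_all,
                      find_stable_transcripts, RNA_BOUNDARIES)

scenario = simulate_scenario(SimulationConfig(seed=1))
tpm, removed = preprocess_counts(scenario.rna.counts, scenario.annotation)

fractions = entity_fractions(tpm, scenario.annotation)
print(fractions.round(3))

classes = classify_all(mean_over_replicates(tpm), scenario.annotation, RNA_BOUNDARIES)
print(classes["class"].value_counts())

report = find_stable_transcripts(tpm, scenario.annotation)
print(report[report["stable"]].round(2))
```

prints

```
          host_fraction  phage_fraction
time_min
0.0               1.000           0.000
1.0               0.876           0.124
4.0               0.628           0.372
7.0               0.419           0.581
20.0              0.182           0.818
class
early     374
late       70
middle     56
Name: count, dtype: int64
         mean_tpm  final_over_t0  stable
gene_id
EC0137   29158.25           0.97    True
EC0742   26341.87           1.09    True
EC0790   46973.40           0.82    True
EC0869   46388.49           1.07    True
```

i.e. the phage's share of the (rRNA-free) transcriptome rises
monotonically to ~82% by 20 min; most phage genes switch on in the
early phase; and exactly the four planted stable host non-coding RNAs
(tmRNA-like hyper-abundant transcripts) pass the stability screen.

The same scenario can be written to disk (`phagedyn simulate --out dir/
--seed 1`) and analysed with the CLI subcommands `tpm`, `classify`,
`stability` and `integrate`.

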