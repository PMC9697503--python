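"""Host-side screens: transcript stability, decay profiles, proteome stability.

During lytic infection the host transcriptome is largely degraded while
the host proteome persists.  This module screens for the exceptions on
the RNA side (transcripts that keep >= 80% of their pre-infection TPM to
the end of the time course while being reasonably abundant) and
summarizes the rule on the protein side (maximal absolute log2 fold
change vs the uninfected sample).  It also provides targeted statistics:
per-gene percent-of-baseline decay curves, time-averaged abundance ratios
between two proteins, and per-time detected-protein counts with proteome
coverage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrices import (
    AbundanceMatrix,
    Unit,
    ValidationError,
    validate_annotation,
)
from .normalize import mean_over_replicates, percent_of_t0


def find_stable_transcripts(
    tpm: AbundanceMatrix,
    annotation: pd.DataFrame,
    min_mean: float = 10.0,
    min_final_frac: float = 0.80,
) -> pd.DataFrame:
    """Screen host transcripts for stability through infection.

    A host gene is *stable* when its mean TPM over the (replicate-
    averaged) time course is at least ``min_mean`` and its TPM at the
    final sampled time is at least ``min_final_frac`` of its TPM at t0.
    Genes with zero TPM at t0 have an undefined ratio and are never
    stable.  Returns one report row per host gene with columns
    ``mean_tpm``, ``final_over_t0`` and ``stable``.
    """
    validate_annotation(annotation)
    if tpm.unit is not Unit.TPM:
        raise ValidationError(f"stability screen expects TPM, got {tpm.unit.value}")
    matrix = mean_over_replicates(tpm)
    times = matrix.times
    if 0.0 not in times:
        raise ValidationError("t0 column required for the stability screen")
    if len(times) < 2:
        raise ValidationError("at least two time points required")
    final = times[-1]
    host = [
        g
        for g in matrix.genes
        if g in annotation.index and annotation.loc[g, "entity"] == "host"
    ]
    df = matrix.data.loc[host]
    mean_tpm = df.mean(axis=1)
    baseline = df[0.0]
    ratio = df[final] / baseline.replace(0, np.nan)
    stable = (mean_tpm >= min_mean) & (ratio >= min_final_frac)
    stable &= ratio.notna()
    report = pd.DataFrame(
        {"mean_tpm": mean_tpm, "final_over_t0": ratio, "stable": stable}
    )
    report.index.name = "gene_id"
    return report


def decay_profile(tpm: AbundanceMatrix, gene_ids: list[str]) -> AbundanceMatrix:
    """Percent-of-t0 decay curves for the requested genes.

    Delegates to :func:`phagedyn.normalize.percent_of_t0` after replicate
    averaging; every curve starts at 100% at t0.
    """
    matrix = mean_over_replicates(tpm)
    unknown = [g for g in gene_ids if g not in matrix.data.index]
    if unknown:
        raise ValidationError(f"unknown gene(s): {unknown}")
    return percent_of_t0(matrix.restrict(gene_ids))


def protein_stability_summary(
    lfq: AbundanceMatrix,
    annotation: pd.DataFrame,
    entity: str = "host",
) -> tuple[pd.Series, dict]:
    """Per-protein maximal |log2 fold change| vs t0 and cohort summary.

    Proteins not detected at t0 are excluded (no baseline).  Times at
    which a protein drops out of detection are skipped in the maximum
    (the statistic measures abundance drift among detected values).
    Returns the per-protein statistic and a summary dict with the cohort
    median, the fraction of proteins staying within two-fold of baseline
    (statistic <= 1), and the cohort size.
    """
    validate_annotation(annotation)
    if lfq.unit is not Unit.LFQ:
        raise ValidationError(f"expected LFQ data, got {lfq.unit.value}")
    matrix = mean_over_replicates(lfq)
    if 0.0 not in matrix.data.columns:
        raise ValidationError("t0 column required")
    genes = [
        g
        for g in matrix.genes
        if g in annotation.index and annotation.loc[g, "entity"] == entity
    ]
    df = matrix.data.loc[genes]
    baseline = df[0.0]
    df = df[baseline.notna() & (baseline > 0)]
    baseline = df[0.0]
    later = df.drop(columns=[0.0])
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(later.div(baseline, axis=0))
    log2fc = log2fc.replace([np.inf, -np.inf], np.nan)
    stat = log2fc.abs().max(axis=1, skipna=True).fillna(0.0)
    stat.name = "max_abs_log2fc"
    summary = {
        "median": float(stat.median()) if len(stat) else float("nan"),
        "fraction_within_twofold": float((stat <= 1.0).mean()) if len(stat) else float("nan"),
        "n": int(len(stat)),
    }
    return stat, summary


def abundance_ratio(lfq: AbundanceMatrix, gene_a: str, gene_b: str) -> float:
    """Fold ratio of time-averaged abundances of two proteins.

    Not-detected values contribute 0 to the time averages; the ratio is
    invariant to a common rescaling of both proteins.
    """
    matrix = mean_over_replicates(lfq)
    for g in (gene_a, gene_b):
        if g not in matrix.data.index:
            raise ValidationError(f"unknown gene {g!r}")
    mean_a = float(matrix.data.loc[gene_a].fillna(0.0).mean())
    mean_b = float(matrix.data.loc[gene_b].fillna(0.0).mean())
    if mean_b == 0:
        raise ValidationError(f"{gene_b!r} has zero time-averaged abundance")
    return mean_a / mean_b


def detected_counts(
    lfq: AbundanceMatrix,
    annotation: pd.DataFrame,
    proteome_sizes: dict[str, int],
) -> pd.DataFrame:
    """Detected-protein counts and proteome coverage per time and entity.

    Operates on the per-sample (unaveraged) LFQ matrix: a protein counts
    as detected at time t if it is detected in at least one replicate.
    ``proteome_sizes`` supplies the annotated proteome size per entity
    for the coverage fraction.  Returns a tidy DataFrame with columns
    ``time_min``, ``entity``, ``n_detected``, ``coverage``.
    """
    validate_annotation(annotation)
    if lfq.unit is not Unit.LFQ:
        raise ValidationError(f"expected LFQ data, got {lfq.unit.value}")
    df = lfq.data
    detected = df.notna() & (df > 0)
    if not lfq.is_replicate_averaged:
        detected = detected.T.groupby(level="time_min").any().T
    entity = annotation.reindex(df.index)["entity"]
    if entity.isna().any():
        missing = entity.index[entity.isna()].tolist()
        raise ValidationError(f"proteins absent from annotation: {missing[:5]}")
    rows = []
    for ent, size in sorted(proteome_sizes.items()):
        sub = detected.loc[entity == ent]
        counts = sub.sum(axis=0)
        for t in sorted(counts.index):
            n = int(counts[t])
            rows.append(
                {"time_min": float(t), "entity": ent, "n_detected": n, "coverage": n / size}
            )
    return pd.DataFrame(rows)
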