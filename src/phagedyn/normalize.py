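"""Preprocessing of infection time-course matrices.

The canonical RNA-seq order of operations is: drop rRNA genes from the
raw counts (they were depleted before sequencing and would distort the
relative scale), normalize to transcripts per million (TPM), then remove
genes whose *raw* mean count across all samples falls below a low-count
threshold from the TPM matrix.  Downstream per-gene normalizations
(z-score, fraction-of-max, percent-of-t0) operate on replicate-averaged
matrices.  Entity fractions ("takeover curves") report the share of total
TPM (or LFQ signal) attributable to phage vs host at each time point.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrices import (
    AbundanceMatrix,
    CountMatrix,
    Unit,
    ValidationError,
    validate_annotation,
)


def remove_biotype(
    counts: CountMatrix, annotation: pd.DataFrame, biotype: str
) -> CountMatrix:
    """Drop all genes of the given biotype (e.g. rRNA); order preserved."""
    validate_annotation(annotation)
    missing = [g for g in counts.genes if g not in annotation.index]
    if missing:
        raise ValidationError(f"genes absent from annotation: {missing[:5]}")
    drop = set(annotation.index[annotation["biotype"] == biotype]) & set(counts.genes)
    keep = [g for g in counts.genes if g not in drop]
    lengths = counts.lengths.loc[keep] if counts.lengths is not None else None
    return CountMatrix(counts.data.loc[keep].copy(), lengths=lengths)


def tpm_normalize(counts: CountMatrix, lengths: pd.Series | None = None) -> AbundanceMatrix:
    """Transcripts-per-million normalization.

    Per sample: ``rate_g = count_g / (length_g / 1000)`` and
    ``TPM_g = rate_g / sum_h rate_h * 1e6``, so every column with at least
    one nonzero count sums to 1e6.  An all-zero sample column stays zero
    and triggers a warning.
    """
    if lengths is None:
        lengths = counts.lengths
    if lengths is None:
        raise ValidationError("gene lengths required for TPM normalization")
    lengths = lengths.reindex(counts.data.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValidationError(f"missing lengths for genes: {missing[:5]}")
    if (lengths < 1).any():
        raise ValidationError("gene lengths must be >= 1")
    rates = counts.data.div(lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    zero_cols = totals[totals == 0].index.tolist()
    if zero_cols:
        warnings.warn(f"all-zero sample column(s): {zero_cols}", stacklevel=2)
        totals = totals.replace(0, np.nan)
    tpm = rates.div(totals, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    return AbundanceMatrix(tpm, Unit.TPM)


def filter_low_counts(
    counts: CountMatrix, tpm: AbundanceMatrix, threshold: float = 1.5
) -> tuple[AbundanceMatrix, list[str]]:
    """Remove low-count genes from a TPM matrix.

    A gene is removed when its arithmetic-mean *raw* count across all
    samples is below ``threshold``.  The removed gene list is returned
    for reporting.
    """
    if set(counts.genes) != set(tpm.genes) or list(counts.data.columns) != list(
        tpm.data.columns
    ):
        raise ValidationError("counts and TPM matrices must share gene and sample indices")
    means = counts.data.mean(axis=1)
    removed = means.index[means < threshold].tolist()
    kept = [g for g in tpm.genes if g not in set(removed)]
    return AbundanceMatrix(tpm.data.loc[kept].copy(), tpm.unit), removed


def mean_over_replicates(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Arithmetic mean per (gene, time) over replicates.

    For LFQ data, not-detected values count as 0 in the mean (detection-
    limit censoring), but a (gene, time) where *all* replicates are
    not-detected stays not-detected.
    """
    if matrix.is_replicate_averaged:
        return AbundanceMatrix(matrix.data.copy(), matrix.unit)
    df = matrix.data
    filled = df.fillna(0.0) if matrix.unit is Unit.LFQ else df
    means = filled.T.groupby(level="time_min").mean().T
    if matrix.unit is Unit.LFQ:
        all_nd = df.isna().T.groupby(level="time_min").all().T
        means = means.mask(all_nd)
    means = means[sorted(means.columns)]
    means.columns = pd.Index(means.columns, name="time_min")
    return AbundanceMatrix(means, matrix.unit)


def zscore_by_gene(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Per-gene z-score over the time course (population standard deviation).

    Constant genes map to all-zero rows.  Expects a replicate-averaged
    matrix, as plotted in expression heatmaps.
    """
    if not matrix.is_replicate_averaged:
        raise ValidationError("z-scoring expects a replicate-averaged matrix")
    df = matrix.data.fillna(0.0)
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0)
    z = df.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return AbundanceMatrix(z, Unit.ZSCORE)


def fraction_of_max(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each gene's profile by its maximum over time (max -> 1)."""
    if not matrix.is_replicate_averaged:
        raise ValidationError("fraction_of_max expects a replicate-averaged matrix")
    df = matrix.data.fillna(0.0)
    peak = df.max(axis=1)
    out = df.div(peak.replace(0, np.nan), axis=0).fillna(0.0)
    return AbundanceMatrix(out, Unit.FRACTION_OF_MAX)


def percent_of_t0(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Express each gene's profile as a percentage of its pre-infection value.

    Genes with value 0 at t0 have no defined baseline; their rows become
    NaN (undefined) rather than infinities, and stability screens must
    exclude them.
    """
    if not matrix.is_replicate_averaged:
        raise ValidationError("percent_of_t0 expects a replicate-averaged matrix")
    if 0.0 not in matrix.data.columns:
        raise ValidationError("t0 (time_min=0) column required for percent_of_t0")
    df = matrix.data.fillna(0.0)
    baseline = df[0.0].replace(0, np.nan)
    out = df.div(baseline, axis=0) * 100.0
    return AbundanceMatrix(out, Unit.PERCENT_OF_T0)


def entity_fractions(
    matrix: AbundanceMatrix,
    annotation: pd.DataFrame,
    method: str = "per_replicate",
) -> pd.DataFrame:
    """Fraction of total abundance per entity (host/phage) over time.

    With ``method="per_replicate"`` fractions are computed per sample and
    then averaged over replicates; with ``method="averaged"`` they are
    computed on the replicate-averaged matrix.  LFQ not-detected entries
    contribute 0.  Returns a DataFrame indexed by time with columns
    ``host_fraction`` and ``phage_fraction`` summing to 1.
    """
    validate_annotation(annotation)
    missing = [g for g in matrix.genes if g not in annotation.index]
    if missing:
        raise ValidationError(f"genes absent from annotation: {missing[:5]}")
    if method not in ("per_replicate", "averaged"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "averaged" or matrix.is_replicate_averaged:
        matrix = mean_over_replicates(matrix)
    df = matrix.data.fillna(0.0)
    entity = annotation.loc[df.index, "entity"]
    sums = df.groupby(entity.to_numpy()).sum()
    sums = sums.reindex(["host", "phage"], fill_value=0.0)
    totals = sums.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValidationError(f"zero total abundance in sample(s): {bad}")
    fracs = sums.div(totals, axis=1).T  # samples x entity
    if fracs.index.nlevels == 2:
        fracs = fracs.groupby(level="time_min").mean()
    fracs = fracs.sort_index()
    fracs.index.name = "time_min"
    fracs.columns = ["host_fraction", "phage_fraction"]
    return fracs


def preprocess_counts(
    counts: CountMatrix,
    annotation: pd.DataFrame,
    low_count_threshold: float = 1.5,
    remove_rrna: bool = True,
) -> tuple[AbundanceMatrix, list[str]]:
    """Standard RNA-seq preprocessing: rRNA removal -> TPM -> low-count filter.

    Returns the filtered per-sample TPM matrix and the list of removed
    low-count genes.
    """
    if remove_rrna:
        counts = remove_biotype(counts, annotation, "rRNA")
    tpm = tpm_normalize(counts)
    return filter_low_counts(counts, tpm, threshold=low_count_threshold)
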