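"""Onset-based early/middle/late classification of phage genes.

A gene's expression onset is the first sampled time at which its
replicate-averaged abundance reaches at least 10% of its maximal value
over the time course (the "detected expression" criterion; LFQ
not-detected counts as 0).  Classes are assigned from the onset relative
to two phase boundaries: onset before ``early_end_min`` -> early; onset
in ``[early_end_min, late_start_min)`` -> middle; onset at or after
``late_start_min`` -> late.  The conventional boundaries are (4, 7)
minutes for the transcriptome and (5, 8) minutes for the proteome, chosen
to bracket the sampled time grids of the two layers.

Because onsets depend only on profile shape, classification is invariant
under positive rescaling of a profile.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .matrices import (
    AbundanceMatrix,
    Unit,
    ValidationError,
    validate_annotation,
)
from .normalize import mean_over_replicates

CLASSES = ("early", "middle", "late")
UNEXPRESSED = "unexpressed"


@dataclasses.dataclass(frozen=True)
class PhaseBoundaries:
    """Infection-phase boundaries in minutes post-infection."""

    early_end_min: float
    late_start_min: float

    def __post_init__(self) -> None:
        if not (0 < self.early_end_min < self.late_start_min):
            raise ValidationError(
                f"boundaries must satisfy 0 < early_end < late_start, "
                f"got ({self.early_end_min}, {self.late_start_min})"
            )


#: conventional boundaries for RNA (sampled at 0/1/4/7/20 min)
RNA_BOUNDARIES = PhaseBoundaries(4.0, 7.0)
#: conventional boundaries for protein (sampled at 0/1/3/5/8/12/20/30 min)
PROTEIN_BOUNDARIES = PhaseBoundaries(5.0, 8.0)


def detect_onset(profile: pd.Series, onset_fraction: float = 0.10) -> float | None:
    """First sampled time with abundance >= onset_fraction * max(profile).

    Returns None for an all-zero (never expressed) profile.
    """
    if len(profile) == 0:
        raise ValidationError("empty profile")
    values = profile.fillna(0.0).sort_index()
    peak = float(values.max())
    if peak <= 0:
        return None
    hit = values[values >= onset_fraction * peak]
    return float(hit.index[0])


def classify_gene(onset_min: float, boundaries: PhaseBoundaries) -> str:
    """Map an onset time to early/middle/late."""
    if onset_min < boundaries.early_end_min:
        return "early"
    if onset_min < boundaries.late_start_min:
        return "middle"
    return "late"


def classify_all(
    matrix: AbundanceMatrix,
    annotation: pd.DataFrame,
    boundaries: PhaseBoundaries,
    entity: str = "phage",
    onset_fraction: float = 0.10,
    min_mean_abundance: float | None = None,
) -> pd.DataFrame:
    """Classify every gene of an entity on one omics layer.

    The matrix is replicate-averaged if necessary.  Genes whose mean
    abundance over the time course falls below ``min_mean_abundance``
    (default 1 for TPM, 0 for LFQ) are excluded before classification,
    mirroring the usual exclusion of barely-expressed genes.  Genes with
    an all-zero profile are labelled ``unexpressed``.

    Returns a DataFrame indexed by gene_id with columns ``onset_min``,
    ``peak_min`` (earliest time of maximal abundance) and ``class``.
    """
    validate_annotation(annotation)
    matrix = mean_over_replicates(matrix)
    genes = [
        g
        for g in matrix.genes
        if g in annotation.index and annotation.loc[g, "entity"] == entity
    ]
    if not genes:
        raise ValidationError(f"no genes of entity {entity!r} in the matrix")
    if min_mean_abundance is None:
        min_mean_abundance = 1.0 if matrix.unit is Unit.TPM else 0.0
    df = matrix.data.loc[genes].fillna(0.0)
    df = df[sorted(df.columns)]
    df = df[df.mean(axis=1) >= min_mean_abundance]

    times = np.asarray(df.columns, dtype=float)
    values = df.to_numpy()
    peaks = values.max(axis=1)
    records = []
    for i, gene in enumerate(df.index):
        if peaks[i] <= 0:
            records.append((gene, np.nan, np.nan, UNEXPRESSED))
            continue
        onset = times[int(np.argmax(values[i] >= onset_fraction * peaks[i]))]
        peak_t = times[int(np.argmax(values[i]))]  # ties -> earliest
        records.append((gene, onset, peak_t, classify_gene(onset, boundaries)))
    out = pd.DataFrame(
        records, columns=["gene_id", "onset_min", "peak_min", "class"]
    ).set_index("gene_id")
    return out


def class_counts(classification: pd.DataFrame) -> pd.Series:
    """Number of genes per temporal class (unexpressed included)."""
    order = list(CLASSES) + [UNEXPRESSED]
    counts = classification["class"].value_counts()
    return counts.reindex([c for c in order if c in counts.index]).astype(int)


def peak_time_tally(classification: pd.DataFrame) -> pd.Series:
    """Count of genes whose expression peaks at each sampled time.

    Unexpressed genes are excluded; the tally sums to the number of
    expressed genes.
    """
    expressed = classification[classification["class"] != UNEXPRESSED]
    tally = expressed["peak_min"].value_counts().sort_index()
    tally.index.name = "time_min"
    tally.name = "n_genes"
    return tally.astype(int)
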