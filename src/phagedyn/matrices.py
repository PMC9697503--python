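"""Core in-memory containers for infection time-course data.

The pipeline operates on three kinds of tables:

* a gene annotation (one row per gene: entity, length, biotype, name),
* an integer gene x sample count matrix (featureCounts-style output), and
* a real-valued gene x sample abundance matrix tagged with a unit
  (TPM, LFQ intensity, or one of the derived per-gene normalizations).

Samples are identified by (time in minutes post-infection, replicate).
Time 0 always means the uninfected culture.  Matrices carry samples as a
two-level pandas column MultiIndex ``(time_min, replicate)``; replicate-
averaged matrices carry a single ``time_min`` level.  For label-free
proteomics (LFQ) data, NaN encodes "not detected", which is distinct from
a measured zero and survives round trips through TSV as ``NA``.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PipelineError):
    """A file does not conform to the expected layout."""


class ValidationError(PipelineError):
    """An in-memory object violates one of its invariants."""


ENTITIES = ("host", "phage")
BIOTYPES = ("mRNA", "rRNA", "tRNA", "ncRNA", "other")

#: names of the two column-index levels used for per-sample matrices
SAMPLE_LEVELS = ("time_min", "replicate")


class Unit(str, enum.Enum):
    """Unit tag of an :class:`AbundanceMatrix`."""

    TPM = "TPM"
    LFQ = "LFQ"
    ZSCORE = "zscore"
    FRACTION_OF_MAX = "fraction_of_max"
    PERCENT_OF_T0 = "percent_of_t0"


@dataclasses.dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one sequencing/MS sample: minutes post-infection and replicate."""

    time_min: float
    replicate: int

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValidationError(f"time_min must be >= 0, got {self.time_min}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")

    def as_tuple(self) -> tuple[float, int]:
        return (float(self.time_min), int(self.replicate))


def sample_index(keys: Iterable[SampleKey | tuple]) -> pd.MultiIndex:
    """Build the canonical two-level sample column index from keys."""
    tuples = []
    for k in keys:
        if isinstance(k, SampleKey):
            tuples.append(k.as_tuple())
        else:
            t, r = k
            tuples.append(SampleKey(float(t), int(r)).as_tuple())
    idx = pd.MultiIndex.from_tuples(tuples, names=list(SAMPLE_LEVELS))
    if idx.duplicated().any():
        dupes = sorted(set(idx[idx.duplicated()]))
        raise ValidationError(f"duplicate (time_min, replicate) sample keys: {dupes}")
    return idx


def _check_gene_index(index: pd.Index) -> None:
    if index.duplicated().any():
        dupes = sorted(set(index[index.duplicated()]))
        raise ValidationError(f"duplicate gene_id values: {dupes}")
    if any((not isinstance(g, str)) or g == "" for g in index):
        raise ValidationError("gene_id values must be non-empty strings")


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (index: gene_id).

    Required columns: ``entity`` (host/phage), ``length_nt`` (>= 1),
    ``biotype`` (mRNA/rRNA/tRNA/ncRNA/other), ``name``.
    """
    required = {"entity", "length_nt", "biotype", "name"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")
    _check_gene_index(annotation.index)
    bad_entity = set(annotation["entity"]) - set(ENTITIES)
    if bad_entity:
        raise ValidationError(f"unknown entity values: {sorted(bad_entity)}")
    bad_biotype = set(annotation["biotype"]) - set(BIOTYPES)
    if bad_biotype:
        raise ValidationError(f"unknown biotype values: {sorted(bad_biotype)}")
    if (annotation["length_nt"] < 1).any():
        offenders = annotation.index[annotation["length_nt"] < 1].tolist()
        raise ValidationError(f"length_nt must be >= 1 for genes: {offenders}")
    return annotation


@dataclasses.dataclass
class CountMatrix:
    """Raw read counts, genes x (time_min, replicate) samples.

    ``lengths`` optionally carries per-gene lengths in nucleotides as
    extracted from the counts file's Length column.
    """

    data: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_gene_index(self.data.index)
        if self.data.columns.nlevels != 2:
            raise ValidationError(
                "CountMatrix columns must be a (time_min, replicate) MultiIndex"
            )
        self.data.columns = self.data.columns.set_names(list(SAMPLE_LEVELS))
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate sample columns")
        if self.data.isna().any().any():
            raise ValidationError("CountMatrix must not contain missing values")
        vals = self.data.to_numpy()
        if (vals < 0).any():
            raise ValidationError("negative counts are not allowed")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be integers")
        self.data = self.data.astype(np.int64)
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.data.index)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()].tolist()
                raise ValidationError(f"missing gene lengths for: {missing}")
            if (self.lengths < 1).any():
                raise ValidationError("gene lengths must be >= 1")
            self.lengths = self.lengths.astype(np.int64)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[SampleKey]:
        return [SampleKey(t, r) for t, r in self.data.columns]

    @property
    def times(self) -> list[float]:
        return sorted(set(self.data.columns.get_level_values("time_min")))


@dataclasses.dataclass
class AbundanceMatrix:
    """Real-valued abundances with a unit tag.

    Columns are either the per-sample two-level ``(time_min, replicate)``
    index or, after replicate averaging, a single ``time_min`` level.
    NaN entries mean "not detected" and are only meaningful for LFQ data.
    """

    data: pd.DataFrame
    unit: Unit

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        _check_gene_index(self.data.index)
        if self.data.columns.nlevels == 2:
            self.data.columns = self.data.columns.set_names(list(SAMPLE_LEVELS))
        elif self.data.columns.nlevels == 1:
            self.data.columns = self.data.columns.set_names("time_min")
        else:
            raise ValidationError("abundance columns must have 1 or 2 levels")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate sample columns")
        self.data = self.data.astype(float)
        if self.unit is not Unit.LFQ and self.unit is not Unit.PERCENT_OF_T0:
            if self.data.isna().any().any():
                raise ValidationError(
                    f"missing values are only allowed for LFQ/percent_of_t0, unit={self.unit.value}"
                )
        if self.unit in (Unit.TPM, Unit.LFQ, Unit.FRACTION_OF_MAX, Unit.PERCENT_OF_T0):
            vals = self.data.to_numpy()
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError(f"negative values not allowed for unit {self.unit.value}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def is_replicate_averaged(self) -> bool:
        return self.data.columns.nlevels == 1

    @property
    def times(self) -> list[float]:
        if self.is_replicate_averaged:
            return sorted(self.data.columns)
        return sorted(set(self.data.columns.get_level_values("time_min")))

    def restrict(self, genes: Sequence[str]) -> "AbundanceMatrix":
        unknown = [g for g in genes if g not in self.data.index]
        if unknown:
            raise ValidationError(f"unknown gene(s): {unknown}")
        return AbundanceMatrix(self.data.loc[list(genes)].copy(), self.unit)


def check_tpm_sums(matrix: AbundanceMatrix, rtol: float = 1e-6) -> None:
    """Assert the TPM invariant: every non-empty column sums to 1e6."""
    if matrix.unit is not Unit.TPM:
        raise ValidationError(f"expected a TPM matrix, got {matrix.unit.value}")
    sums = matrix.data.sum(axis=0)
    nonzero = sums[sums > 0]
    if not np.allclose(nonzero.to_numpy(), 1e6, rtol=rtol):
        worst = (nonzero - 1e6).abs().idxmax()
        raise ValidationError(
            f"TPM column {worst} sums to {nonzero[worst]!r}, expected 1e6"
        )
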