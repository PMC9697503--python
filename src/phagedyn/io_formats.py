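"""Readers and writers for the tabular formats the pipeline touches.

Supported inputs:

* featureCounts-style count tables (TSV; leading ``#`` comment lines;
  fixed columns Geneid/Chr/Start/End/Strand/Length followed by one column
  per sample),
* GFF3 gene annotations (1-based inclusive coordinates; parsed with
  :mod:`gffutils`), and
* MaxQuant ``proteinGroups``-style LFQ tables (zero/blank intensities are
  not-detected; reverse and contaminant rows are dropped).

All outputs are plain TSV with a header row.  Reals are written with 12
significant digits so that write/read round trips preserve values to that
precision; integer matrices round-trip bit-identically.  LFQ not-detected
entries are written as ``NA`` and re-read as not-detected.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import gffutils
import numpy as np
import pandas as pd

from .matrices import (
    AbundanceMatrix,
    CountMatrix,
    FormatError,
    SampleKey,
    Unit,
    sample_index,
    validate_annotation,
)

FEATURECOUNTS_COLUMNS = ["Geneid", "Chr", "Start", "End", "Strand", "Length"]

_SAMPLE_NAME_RE = re.compile(r"^t(?P<time>\d+(?:\.\d+)?)(?:_r(?P<rep>\d+))?$")


def _norm_key(key: SampleKey | tuple) -> SampleKey:
    if isinstance(key, SampleKey):
        return key
    t, r = key
    return SampleKey(float(t), int(r))


def format_sample_name(time_min: float, replicate: int | None = None) -> str:
    """Canonical column name for a sample, e.g. ``t7_r2`` or ``t7`` (averaged)."""
    t = f"{time_min:g}"
    return f"t{t}" if replicate is None else f"t{t}_r{replicate}"


def infer_sample_map(columns) -> dict[str, SampleKey]:
    """Recover a sample map from canonical ``t<time>_r<rep>`` column names."""
    out: dict[str, SampleKey] = {}
    for col in columns:
        m = _SAMPLE_NAME_RE.match(str(col))
        if m:
            rep = int(m.group("rep")) if m.group("rep") else 1
            out[col] = SampleKey(float(m.group("time")), rep)
    if not out:
        raise FormatError(f"no sample columns of the form t<min>_r<rep> among {list(columns)}")
    return out


def read_counts_table(
    path: str | Path, sample_map: Mapping[str, SampleKey | tuple] | None = None
) -> CountMatrix:
    """Read a featureCounts-style TSV into a :class:`CountMatrix`.

    ``sample_map`` maps file column names to sample keys; if omitted, the
    canonical ``t<min>_r<rep>`` naming written by :func:`write_table` is
    assumed.  Column order of the file is preserved.  Per-gene lengths are
    taken from the mandatory ``Length`` column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in FEATURECOUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"counts table {path} is missing mandatory column(s): {missing}")
    if sample_map is None:
        extra = [c for c in df.columns if c not in FEATURECOUNTS_COLUMNS]
        sample_map = infer_sample_map(extra)
    absent = [c for c in sample_map if c not in df.columns]
    if absent:
        raise FormatError(f"sample column(s) not present in {path}: {absent}")

    genes = df["Geneid"]
    if genes.duplicated().any():
        dupes = sorted(set(genes[genes.duplicated()]))
        raise FormatError(f"duplicate Geneid values: {dupes}")

    # preserve file order of the mapped sample columns
    sample_cols = [c for c in df.columns if c in sample_map]
    counts = {}
    for col in sample_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-integer count {df[col].iloc[i]!r} at row {i} "
                f"(gene {genes.iloc[i]!r}), column {col!r}"
            )
        if (vals < 0).any():
            i = int(np.flatnonzero((vals < 0).to_numpy())[0])
            raise FormatError(f"negative count at row {i}, column {col!r}")
        counts[col] = vals.astype(np.int64)

    lengths = pd.to_numeric(df["Length"], errors="coerce")
    if lengths.isna().any() or (lengths < 1).any():
        raise FormatError("Length column must contain positive integers")

    data = pd.DataFrame(counts)
    data.index = pd.Index(genes, name="gene_id")
    data.columns = sample_index([_norm_key(sample_map[c]) for c in sample_cols])
    lengths.index = data.index
    return CountMatrix(data, lengths=lengths.astype(np.int64))


def _scan_duplicate_gene_ids(path: Path) -> list[str]:
    seen: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "gene":
                continue
            m = re.search(r"(?:^|;)ID=([^;]+)", parts[8])
            if m:
                seen[m.group(1)] = seen.get(m.group(1), 0) + 1
    return sorted(gid for gid, n in seen.items() if n > 1)


def read_gff3_annotation(path: str | Path, entity: str) -> pd.DataFrame:
    """Read gene features from a GFF3 file into an annotation table.

    One record per ``gene`` feature.  ``length_nt = end - start + 1``
    (GFF3 coordinates are 1-based inclusive).  Biotype comes from a
    ``gene_biotype`` or ``biotype`` attribute when present, else "other";
    the display name from ``Name``/``gene``, else the ID.
    """
    path = Path(path)
    dupes = _scan_duplicate_gene_ids(path)
    if dupes:
        raise FormatError(f"duplicate gene ID(s) in {path}: {dupes}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    records = []
    for feat in db.features_of_type("gene"):
        if feat.end < feat.start:
            raise FormatError(
                f"gene {feat.id!r}: end ({feat.end}) < start ({feat.start})"
            )
        biotype = (
            feat.attributes.get("gene_biotype") or feat.attributes.get("biotype") or ["other"]
        )[0]
        if biotype not in ("mRNA", "rRNA", "tRNA", "ncRNA"):
            biotype = "other"
        name = (feat.attributes.get("Name") or feat.attributes.get("gene") or [feat.id])[0]
        records.append(
            {
                "gene_id": feat.id,
                "entity": entity,
                "length_nt": feat.end - feat.start + 1,
                "biotype": biotype,
                "name": name,
            }
        )
    if not records:
        raise FormatError(f"no gene features found in {path}")
    annotation = pd.DataFrame(records).set_index("gene_id")
    return validate_annotation(annotation)


# candidate identifier columns of a proteinGroups-style table, in priority order
_LFQ_ID_COLUMNS = ("Gene names", "Majority protein IDs", "Protein IDs")
_LFQ_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Contaminant")


def read_lfq_table(
    path: str | Path,
    sample_map: Mapping[str, SampleKey | tuple] | None = None,
    id_column: str | None = None,
) -> AbundanceMatrix:
    """Read a proteinGroups-style LFQ table into an LFQ AbundanceMatrix.

    Zero, blank, and ``NA`` intensity cells are stored as not-detected
    (NaN).  Rows flagged ``+`` in Reverse / Potential contaminant columns
    are dropped when those columns exist.  For multi-entry identifier
    cells (``a;b``) the first listed name is used.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for flag in _LFQ_FLAG_COLUMNS:
        if flag in df.columns:
            df = df[df[flag].fillna("") != "+"]
    if id_column is None:
        id_column = next((c for c in _LFQ_ID_COLUMNS if c in df.columns), df.columns[0])
    elif id_column not in df.columns:
        raise FormatError(f"identifier column {id_column!r} not in {path}")
    ids = df[id_column].fillna("").str.split(";").str[0]
    if (ids == "").any():
        raise FormatError(f"empty protein identifier(s) in column {id_column!r}")
    if ids.duplicated().any():
        dupes = sorted(set(ids[ids.duplicated()]))
        raise FormatError(f"duplicate protein identifiers after flag filtering: {dupes}")

    if sample_map is None:
        candidates = {}
        for col in df.columns:
            name = col[len("LFQ intensity "):] if col.startswith("LFQ intensity ") else col
            m = _SAMPLE_NAME_RE.match(name)
            if m:
                rep = int(m.group("rep")) if m.group("rep") else 1
                candidates[col] = SampleKey(float(m.group("time")), rep)
        if not candidates:
            raise FormatError(f"could not infer LFQ sample columns in {path}")
        sample_map = candidates
    absent = [c for c in sample_map if c not in df.columns]
    if absent:
        raise FormatError(f"sample column(s) not present in {path}: {absent}")

    sample_cols = [c for c in df.columns if c in sample_map]
    values = {}
    for col in sample_cols:
        raw = df[col].replace({"": np.nan, "NA": np.nan, "NaN": np.nan})
        vals = pd.to_numeric(raw, errors="coerce")
        numeric_bad = raw.notna() & vals.isna()
        if numeric_bad.any():
            i = int(np.flatnonzero(numeric_bad.to_numpy())[0])
            raise FormatError(f"non-numeric intensity {raw.iloc[i]!r} in column {col!r}")
        vals[vals <= 0] = np.nan  # MaxQuant writes 0 for not-detected
        values[col] = vals
    data = pd.DataFrame(values)
    data.index = pd.Index(ids, name="gene_id")
    data.columns = sample_index([_norm_key(sample_map[c]) for c in sample_cols])
    return AbundanceMatrix(data, Unit.LFQ)


def _sample_column_names(columns) -> list[str]:
    if columns.nlevels == 2:
        return [format_sample_name(t, int(r)) for t, r in columns]
    return [format_sample_name(t) for t in columns]


def write_table(obj, path: str | Path) -> Path:
    """Write a matrix or result table as TSV.

    * CountMatrix: featureCounts layout (placeholder Chr/Start/End/Strand)
      so that :func:`read_counts_table` round-trips it.
    * AbundanceMatrix: gene_id + one column per sample; NaN -> ``NA``.
    * DataFrame / Series (classifications, reports): index written under
      its name (default ``gene_id``).
    """
    path = Path(path)
    if isinstance(obj, CountMatrix):
        lengths = (
            obj.lengths if obj.lengths is not None else pd.Series(1, index=obj.data.index)
        )
        out = pd.DataFrame(
            {
                "Geneid": obj.data.index,
                "Chr": ".",
                "Start": 1,
                "End": lengths.to_numpy(),
                "Strand": "+",
                "Length": lengths.to_numpy(),
            }
        )
        body = obj.data.copy()
        body.columns = _sample_column_names(obj.data.columns)
        out = pd.concat([out.reset_index(drop=True), body.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)
    elif isinstance(obj, AbundanceMatrix):
        body = obj.data.copy()
        body.columns = _sample_column_names(obj.data.columns)
        body.index.name = "gene_id"
        body.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")
    elif isinstance(obj, (pd.DataFrame, pd.Series)):
        frame = obj.to_frame() if isinstance(obj, pd.Series) else obj
        frame = frame.copy()
        if frame.index.name is None and not isinstance(frame.index, pd.RangeIndex):
            frame.index.name = "gene_id"
        frame.to_csv(
            path,
            sep="\t",
            na_rep="NA",
            float_format="%.12g",
            index=not isinstance(frame.index, pd.RangeIndex),
        )
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    return path


def read_abundance_table(
    path: str | Path,
    unit: Unit | str,
    sample_map: Mapping[str, SampleKey | tuple] | None = None,
) -> AbundanceMatrix:
    """Read back an abundance TSV written by :func:`write_table`.

    Column names follow the canonical ``t<min>_r<rep>`` (per-sample) or
    ``t<min>`` (replicate-averaged) pattern unless ``sample_map`` is given.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index.name = "gene_id"
    df.index = df.index.astype(str)
    if sample_map is not None:
        cols = [c for c in df.columns if c in sample_map]
        data = df[cols]
        data.columns = sample_index([_norm_key(sample_map[c]) for c in cols])
        return AbundanceMatrix(data, Unit(unit))
    parsed = []
    averaged = None
    for col in df.columns:
        m = _SAMPLE_NAME_RE.match(str(col))
        if not m:
            raise FormatError(f"unparseable sample column {col!r} in {path}")
        col_avg = m.group("rep") is None
        if averaged is None:
            averaged = col_avg
        elif averaged != col_avg:
            raise FormatError(f"mixed averaged/per-replicate columns in {path}")
        parsed.append(
            float(m.group("time")) if col_avg else (float(m.group("time")), int(m.group("rep")))
        )
    data = df.copy()
    if averaged:
        data.columns = pd.Index(parsed, name="time_min")
    else:
        data.columns = sample_index(parsed)
    return AbundanceMatrix(data, Unit(unit))
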