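"""Transcriptome-proteome integration of temporal gene classes.

Joins per-gene RNA and protein classifications through a user-supplied
identifier map, tabulates the full 3x3 class contingency (the richer
form of the usual class-overlap Venn diagrams), extracts temporally
*decoupled* genes (by default: early transcript but late protein,
implying post-transcriptional regulation), and orders gene-cascade
events by onset times on both layers.

Genes classified on only one layer (e.g. proteins never detected) are
excluded from the join but reported via the module logger rather than
dropped silently.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .matrices import ValidationError
from .temporal_classify import CLASSES, UNEXPRESSED

logger = logging.getLogger(__name__)


def join_layers(
    rna_classification: pd.DataFrame,
    protein_classification: pd.DataFrame,
    id_map: Mapping[str, str] | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join RNA- and protein-level classifications gene by gene.

    ``id_map`` maps RNA gene_id to the protein identifier used in the
    protein table (one-to-one; a DataFrame with columns ``gene_id`` /
    ``protein_id`` is also accepted).  Without a map, identifiers are
    assumed shared.  Entries present on only one layer, and genes
    labelled unexpressed on either layer, are excluded from the result;
    their counts are logged.

    Returns a DataFrame indexed by gene_id with columns ``rna_class``,
    ``protein_class``, ``rna_onset_min``, ``protein_onset_min`` and
    ``decoupled`` (early transcript, late protein).
    """
    if isinstance(id_map, pd.DataFrame):
        if not {"gene_id", "protein_id"} <= set(id_map.columns):
            raise ValidationError("id_map DataFrame needs gene_id and protein_id columns")
        pairs = list(zip(id_map["gene_id"], id_map["protein_id"]))
    elif id_map is None:
        pairs = [(g, g) for g in rna_classification.index]
    else:
        pairs = list(id_map.items())

    genes = pd.Series([g for g, _ in pairs])
    prots = pd.Series([p for _, p in pairs])
    ambiguous = sorted(set(genes[genes.duplicated()]) | set(prots[prots.duplicated()]))
    if ambiguous:
        raise ValidationError(f"ambiguous (one-to-many) id_map entries: {ambiguous}")

    records = []
    n_rna_only = n_protein_only = n_unclassified = 0
    mapped_proteins = set()
    for gene, prot in pairs:
        in_rna = gene in rna_classification.index
        in_prot = prot in protein_classification.index
        mapped_proteins.add(prot)
        if in_rna and not in_prot:
            n_rna_only += 1
            continue
        if in_prot and not in_rna:
            n_protein_only += 1
            continue
        if not in_rna and not in_prot:
            continue
        rna_row = rna_classification.loc[gene]
        prot_row = protein_classification.loc[prot]
        if rna_row["class"] == UNEXPRESSED or prot_row["class"] == UNEXPRESSED:
            n_unclassified += 1
            continue
        records.append(
            {
                "gene_id": gene,
                "rna_class": rna_row["class"],
                "protein_class": prot_row["class"],
                "rna_onset_min": float(rna_row["onset_min"]),
                "protein_onset_min": float(prot_row["onset_min"]),
            }
        )
    n_rna_only += sum(1 for g in rna_classification.index if g not in {p[0] for p in pairs})
    n_protein_only += sum(
        1 for p in protein_classification.index if p not in mapped_proteins
    )
    if n_rna_only or n_protein_only or n_unclassified:
        logger.warning(
            "join_layers: %d RNA-only, %d protein-only, %d unexpressed entries excluded",
            n_rna_only,
            n_protein_only,
            n_unclassified,
        )
    if not records:
        logger.warning("join_layers: empty intersection between layers")
        return pd.DataFrame(
            columns=[
                "rna_class",
                "protein_class",
                "rna_onset_min",
                "protein_onset_min",
                "decoupled",
            ],
            index=pd.Index([], name="gene_id"),
        )
    out = pd.DataFrame(records).set_index("gene_id")
    out["decoupled"] = (out["rna_class"] == "early") & (out["protein_class"] == "late")
    return out


def class_overlap(comparisons: pd.DataFrame) -> pd.DataFrame:
    """3x3 contingency of RNA class x protein class over shared genes.

    Row sums equal the RNA class sizes among shared genes; column sums
    the protein class sizes; the grand total the shared-cohort size.
    """
    table = pd.crosstab(comparisons["rna_class"], comparisons["protein_class"])
    table = table.reindex(index=list(CLASSES), columns=list(CLASSES), fill_value=0)
    table.index.name = "rna_class"
    table.columns.name = "protein_class"
    return table


def decoupled_genes(
    comparisons: pd.DataFrame,
    rna_class: str = "early",
    protein_class: str = "late",
) -> list[str]:
    """Genes with the given (RNA class, protein class) combination.

    Sorted by the protein-minus-RNA onset lag, largest first (the most
    strongly delayed genes lead the list).
    """
    hits = comparisons[
        (comparisons["rna_class"] == rna_class)
        & (comparisons["protein_class"] == protein_class)
    ].copy()
    hits["lag"] = hits["protein_onset_min"] - hits["rna_onset_min"]
    hits = hits.sort_index().sort_values("lag", ascending=False, kind="stable")
    return list(hits.index)


def cascade_table(comparisons: pd.DataFrame, gene_ids: list[str]) -> pd.DataFrame:
    """Ordered event table for a gene cascade.

    Rows are sorted by (RNA onset, protein onset); ``onset_inverted``
    flags genes whose protein onset precedes the RNA onset, which is
    biologically implausible and usually indicates an id-map or noise
    problem.
    """
    unknown = [g for g in gene_ids if g not in comparisons.index]
    if unknown:
        raise ValidationError(f"gene(s) absent from the joined table: {unknown}")
    table = comparisons.loc[gene_ids, ["rna_onset_min", "protein_onset_min"]].copy()
    table["onset_inverted"] = table["protein_onset_min"] < table["rna_onset_min"]
    return table.sort_values(["rna_onset_min", "protein_onset_min"])
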