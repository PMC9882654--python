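"""Intron phases, protein-coordinate mapping, and cross-species homology.

An intron's phase is its position relative to codon boundaries: phase 0
introns fall between codons, phase 1 between the first and second
nucleotide of a codon, phase 2 between the second and third.  Two introns
from different genes are homologous when they occupy the same amino-acid
position in a shared protein alignment and have the same phase.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import pandas as pd

from .io import AlignedSet, GeneModel, RasevolError


@dataclass
class IntronRecord:
    gene_id: str
    ordinal: int          # 1-based index in transcript order
    cds_offset: int       # coding nucleotides preceding the intron
    phase: int            # cds_offset mod 3
    protein_position: int  # interrupted residue (phase 1/2) or the residue
                           # following the boundary (phase 0); 1-based
    boundary: bool        # True iff phase 0 (falls between codons)


@dataclass
class ProjectedIntron:
    record: IntronRecord
    alignment_column: int


@dataclass
class IntronHomologyGroup:
    label: str
    alignment_column: int
    phase: int
    members: list[tuple[str, int]]  # (gene_id, ordinal)


def compute_introns(gene_model: GeneModel) -> list[IntronRecord]:
    """One :class:`IntronRecord` per inter-exon junction of a complete CDS."""
    if not gene_model.complete_cds:
        raise RasevolError(
            f"gene {gene_model.gene_id!r}: incomplete CDS "
            f"(coding length {gene_model.coding_length} not divisible by 3)"
        )
    records = []
    offset = 0
    lengths = gene_model.exon_lengths
    for ordinal, length in enumerate(lengths[:-1], start=1):
        offset += length
        phase = offset % 3
        protein_position = offset // 3 + 1
        records.append(IntronRecord(
            gene_id=gene_model.gene_id, ordinal=ordinal, cds_offset=offset,
            phase=phase, protein_position=protein_position,
            boundary=phase == 0,
        ))
    return records


def project_introns(intron_records: list[IntronRecord],
                    aligned_set: AlignedSet,
                    row_of_gene: dict[str, str] | None = None
                    ) -> list[ProjectedIntron]:
    """Map intron protein positions onto alignment columns, per row.

    ``row_of_gene`` maps gene ids to alignment row ids; by default the gene
    id is the row id.  A phase-1/2 intron projects to the column of the
    interrupted residue; a phase-0 intron to the column of the residue
    following the boundary.
    """
    projected = []
    for rec in intron_records:
        row_id = (row_of_gene or {}).get(rec.gene_id, rec.gene_id)
        try:
            ungapped_len = len(aligned_set.ungapped(row_id))
        except KeyError:
            raise RasevolError(
                f"gene {rec.gene_id!r}: no alignment row {row_id!r}"
            ) from None
        if rec.protein_position > ungapped_len:
            raise RasevolError(
                f"gene {rec.gene_id!r}: intron at protein position "
                f"{rec.protein_position} exceeds the {ungapped_len}-residue "
                f"aligned protein (CDS/protein length mismatch?)"
            )
        column = aligned_set.column_of(row_id, rec.protein_position)
        projected.append(ProjectedIntron(record=rec, alignment_column=column))
    return projected


def check_cds_protein_consistency(gene_model: GeneModel,
                                  protein_length: int) -> None:
    """CDS length must equal 3×(protein length + 1) (stop codon included)
    or 3×protein length (stop codon absent)."""
    n = gene_model.coding_length
    if n not in (3 * protein_length, 3 * (protein_length + 1)):
        raise RasevolError(
            f"gene {gene_model.gene_id!r}: coding length {n} inconsistent "
            f"with a {protein_length}-residue protein"
        )


def cluster_homologous(projected: list[ProjectedIntron]
                       ) -> list[IntronHomologyGroup]:
    """Group projected introns by exact (alignment column, phase) key.

    Phase-0 boundaries only ever group with other phase-0 boundaries (the
    phase is part of the key), and singleton groups represent
    lineage-specific introns.
    """
    groups: dict[tuple[int, int], list[tuple[str, int]]] = {}
    for proj in projected:
        key = (proj.alignment_column, proj.record.phase)
        groups.setdefault(key, []).append(
            (proj.record.gene_id, proj.record.ordinal)
        )
    out = []
    for (column, phase), members in groups.items():
        out.append(IntronHomologyGroup(
            label="", alignment_column=column, phase=phase,
            members=sorted(members),
        ))
    # ascending column; equal columns ordered by phase
    out.sort(key=lambda g: (g.alignment_column, g.phase))
    return out


def _letters(index: int) -> str:
    """0 → a, 25 → z, 26 → aa, 27 → ab, ..."""
    alphabet = string.ascii_lowercase
    label = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        label = alphabet[rem] + label
    return label


def label_groups(groups: list[IntronHomologyGroup]
                 ) -> list[IntronHomologyGroup]:
    """Assign letters a, b, c, ... by ascending alignment column."""
    ordered = sorted(groups, key=lambda g: (g.alignment_column, g.phase))
    for i, group in enumerate(ordered):
        group.label = _letters(i)
    return ordered


def intron_homology_table(projected: list[ProjectedIntron],
                          groups: list[IntronHomologyGroup]) -> pd.DataFrame:
    """Machine-readable intron homology table (one row per intron)."""
    label_of: dict[tuple[str, int], str] = {}
    column_of: dict[tuple[str, int], int] = {}
    for group in groups:
        for member in group.members:
            label_of[member] = group.label
            column_of[member] = group.alignment_column
    rows = []
    for proj in projected:
        rec = proj.record
        rows.append({
            "gene_id": rec.gene_id,
            "ordinal": rec.ordinal,
            "cds_offset": rec.cds_offset,
            "phase": rec.phase,
            "protein_position": rec.protein_position,
            "column": proj.alignment_column,
            "group_label": label_of.get((rec.gene_id, rec.ordinal), ""),
        })
    return pd.DataFrame(rows)
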