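"""Sequence, gene-model and alignment I/O.

All coordinates follow two conventions used throughout the package:
genomic spans are 0-based half-open; protein residue positions are 1-based
(so that "residues 1-166" means the first 166 amino acids).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

#: The 20 standard amino acids plus the unknown-residue placeholder.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_RESIDUES = AMINO_ACIDS | {"X"}
GAP = "-"


class RasevolError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(RasevolError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Protein records
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    """One ortholog protein sequence with identity and clade metadata."""

    id: str
    residues: str
    species: str = ""
    clade_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ParseError(f"invalid record id {self.id!r}")
        if not self.residues:
            raise ParseError(f"record {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in ALLOWED_RESIDUES:
                raise ParseError(
                    f"record {self.id!r}: residue {aa!r} at position {pos} "
                    f"is outside the amino-acid alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)


_TAG_SPLIT = re.compile(r"\s+(?=\w+=)")


def _parse_header_tags(description: str) -> dict[str, str]:
    """Parse ``key=value`` tags from a FASTA description.

    Values may contain spaces (``species=Homo sapiens``); a new tag starts at
    whitespace followed by ``word=``.
    """
    tags: dict[str, str] = {}
    for chunk in _TAG_SPLIT.split(description):
        if "=" in chunk:
            key, value = chunk.split("=", 1)
            tags[key.strip()] = value.strip()
    return tags


def _as_handle(source):
    if hasattr(source, "read"):
        return source
    text = str(source)
    if not text or "\n" in text or text.lstrip().startswith(">"):
        return StringIO(text)
    return open(text)


def read_fasta(source) -> list[ProteinRecord]:
    """Read protein FASTA into :class:`ProteinRecord` objects.

    Headers may carry ``species=`` and ``clade=`` key-value tags after the id.
    A single trailing ``*`` (stop) is stripped with a warning.  Raises
    :class:`ParseError` on an empty source, duplicate ids, or residues
    outside the alphabet.
    """
    handle = _as_handle(source)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(handle, "fasta"):
        if entry.id in seen:
            raise ParseError(f"duplicate record id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            warnings.warn(f"record {entry.id!r}: stripped trailing stop '*'")
            seq = seq[:-1]
        tags = _parse_header_tags(entry.description)
        records.append(
            ProteinRecord(
                id=entry.id,
                residues=seq,
                species=tags.get("species", ""),
                clade_label=tags.get("clade"),
            )
        )
    if not records:
        raise ParseError("no FASTA records found in source")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as FASTA, embedding species/clade tags in the header."""
    with open(path, "w") as out:
        for rec in records:
            header = rec.id
            if rec.species:
                header += f" species={rec.species}"
            if rec.clade_label:
                header += f" clade={rec.clade_label}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Coding-exon structure of one gene.

    ``coding_exons`` are (start, end) genomic spans, 0-based half-open,
    listed 5'→3' in transcript orientation (i.e. descending genomic
    coordinates on the '−' strand).
    """

    gene_id: str
    region_id: str
    strand: str
    coding_exons: list[tuple[int, int]]
    complete_cds: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ParseError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if not self.coding_exons:
            raise ParseError(f"gene {self.gene_id!r}: no coding exons")
        for start, end in self.coding_exons:
            if end <= start:
                raise ParseError(
                    f"gene {self.gene_id!r}: empty or inverted exon span ({start}, {end})"
                )
        by_coord = sorted(self.coding_exons)
        for (s1, e1), (s2, e2) in zip(by_coord, by_coord[1:]):
            if s2 < e1:
                raise ParseError(
                    f"gene {self.gene_id!r}: overlapping exons ({s1}, {e1}) and ({s2}, {e2})"
                )
        expected = by_coord if self.strand == "+" else by_coord[::-1]
        if list(self.coding_exons) != expected:
            raise ParseError(
                f"gene {self.gene_id!r}: exons not in transcript order for strand {self.strand}"
            )
        self.complete_cds = self.coding_length % 3 == 0

    @property
    def exon_lengths(self) -> list[int]:
        return [end - start for start, end in self.coding_exons]

    @property
    def coding_length(self) -> int:
        return sum(self.exon_lengths)


def _gene_models_from_rows(rows) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    for gene_id, region_id, strand, start, end, rank in rows:
        info = genes.setdefault(gene_id, {"region": region_id, "strand": strand, "exons": []})
        if info["region"] != region_id:
            raise ParseError(f"gene {gene_id!r}: mixed region_ids "
                             f"({info['region']!r} vs {region_id!r})")
        if info["strand"] != strand:
            raise ParseError(f"gene {gene_id!r}: inconsistent strand")
        info["exons"].append((rank, (int(start), int(end))))
    models = []
    for gene_id, info in genes.items():
        spans = [span for _, span in sorted(info["exons"])]
        models.append(
            GeneModel(gene_id=gene_id, region_id=info["region"],
                      strand=info["strand"], coding_exons=spans)
        )
    return models


def _read_gene_model_tsv(lines: list[str]) -> list[GeneModel]:
    header = lines[0].rstrip("\n").split("\t")
    required = ["gene_id", "region_id", "strand", "start", "end", "rank"]
    if header[: len(required)] != required:
        raise ParseError(
            f"gene-model TSV header must start with {required}, got {header}"
        )
    rows = []
    for line in lines[1:]:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        gene_id, region_id, strand, start, end, rank = fields[:6]
        rows.append((gene_id, region_id, strand, int(start), int(end), int(rank)))
    return _gene_models_from_rows(rows)


_GFF_PARENT = re.compile(r"(?:^|;)\s*Parent=([^;]+)")


def _read_gene_model_gff3(lines: list[str]) -> list[GeneModel]:
    """Read a GFF3 subset: CDS features grouped by their Parent attribute.

    GFF3 coordinates are 1-based inclusive and are converted to 0-based
    half-open here.  Transcript order is genomic order on '+' and reversed
    on '−'.
    """
    grouped: dict[str, dict] = {}
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"malformed GFF3 line: {line!r}")
        seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
        if ftype != "CDS":
            continue
        m = _GFF_PARENT.search(attrs)
        if not m:
            raise ParseError(f"CDS feature without Parent attribute: {line!r}")
        parent = m.group(1)
        info = grouped.setdefault(parent, {"region": seqid, "strand": strand, "spans": []})
        if info["region"] != seqid:
            raise ParseError(f"gene {parent!r}: mixed region_ids")
        info["spans"].append((int(start) - 1, int(end)))
    models = []
    for gene_id, info in grouped.items():
        spans = sorted(info["spans"])
        if info["strand"] == "-":
            spans = spans[::-1]
        models.append(
            GeneModel(gene_id=gene_id, region_id=info["region"],
                      strand=info["strand"], coding_exons=spans)
        )
    return models


def read_gene_models(source) -> list[GeneModel]:
    """Read gene models from the package's TSV format or a GFF3 subset.

    The TSV carries header ``gene_id region_id strand start end rank`` with
    0-based half-open exon spans; the GFF3 path uses CDS features grouped by
    ``Parent``.  Exons are returned 5'→3' in transcript orientation and
    ``complete_cds`` is set from the mod-3 check.
    """
    handle = _as_handle(source)
    lines = handle.read().splitlines()
    if not lines:
        raise ParseError("empty gene-model source")
    if lines[0].startswith("##gff") or (lines[0].count("\t") == 8 and not
                                        lines[0].startswith("gene_id")):
        return _read_gene_model_gff3(lines)
    return _read_gene_model_tsv(lines)


def write_gene_models(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as out:
        out.write("gene_id\tregion_id\tstrand\tstart\tend\trank\n")
        for model in models:
            for rank, (start, end) in enumerate(model.coding_exons, start=1):
                out.write(f"{model.gene_id}\t{model.region_id}\t{model.strand}"
                          f"\t{start}\t{end}\t{rank}\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

class AlignedSet:
    """A gapped protein alignment with residue↔column maps per row.

    Rows must be equal length; every column must contain at least one
    non-gap symbol.  Residue indices are 1-based within the ungapped
    sequence; alignment columns are 0-based.
    """

    def __init__(self, row_ids: Sequence[str], rows: Sequence[str]):
        if len(row_ids) != len(rows):
            raise ParseError("row_ids and rows differ in length")
        if len(set(row_ids)) != len(row_ids):
            raise ParseError("duplicate row ids in alignment")
        if not rows:
            raise ParseError("empty alignment")
        width = len(rows[0])
        for rid, row in zip(row_ids, rows):
            if len(row) != width:
                raise ParseError(f"row {rid!r}: length {len(row)} != {width}")
        if width == 0:
            raise ParseError("alignment has zero columns")
        for col in range(width):
            if all(row[col] == GAP for row in rows):
                raise ParseError(f"alignment column {col} is all gaps")
        self.row_ids = list(row_ids)
        self.rows = [row.upper() for row in rows]
        self._index = {rid: i for i, rid in enumerate(self.row_ids)}
        # per-row maps: columns holding residue k (0-based list), and
        # 1-based residue index per column (0 where the column is a gap)
        self._cols_of: dict[str, list[int]] = {}
        self._res_at: dict[str, list[int]] = {}
        for rid, row in zip(self.row_ids, self.rows):
            cols, res_at, k = [], [], 0
            for col, sym in enumerate(row):
                if sym == GAP:
                    res_at.append(0)
                else:
                    k += 1
                    cols.append(col)
                    res_at.append(k)
            self._cols_of[rid] = cols
            self._res_at[rid] = res_at

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_fasta(cls, source) -> "AlignedSet":
        handle = _as_handle(source)
        ids, rows = [], []
        for entry in SeqIO.parse(handle, "fasta"):
            ids.append(entry.id)
            rows.append(str(entry.seq).upper())
        return cls(ids, rows)

    # -- basic accessors --------------------------------------------------

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self._index[row_id]]
        except KeyError:
            raise KeyError(f"unknown row id {row_id!r}") from None

    def ungapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    # -- coordinate maps --------------------------------------------------

    def column_of(self, row_id: str, residue_index: int) -> int:
        """0-based alignment column holding 1-based residue ``residue_index``."""
        cols = self._cols_of.get(row_id)
        if cols is None:
            raise KeyError(f"unknown row id {row_id!r}")
        if not 1 <= residue_index <= len(cols):
            raise IndexError(
                f"row {row_id!r}: residue index {residue_index} out of range "
                f"1..{len(cols)}"
            )
        return cols[residue_index - 1]

    def residue_at(self, row_id: str, column: int) -> int | None:
        """1-based residue index at ``column``, or None if the row gaps there."""
        res_at = self._res_at.get(row_id)
        if res_at is None:
            raise KeyError(f"unknown row id {row_id!r}")
        if not 0 <= column < self.n_columns:
            raise IndexError(f"column {column} out of range 0..{self.n_columns - 1}")
        idx = res_at[column]
        return idx if idx else None

    # -- output -----------------------------------------------------------

    def to_fasta(self, path=None) -> str | None:
        text = "".join(f">{rid}\n{row}\n" for rid, row in zip(self.row_ids, self.rows))
        if path is None:
            return text
        Path(path).write_text(text)
        return None
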