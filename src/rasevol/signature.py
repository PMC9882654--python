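"""Switch-region signature scanning and conservation analysis.

Two short G-domain blocks overlap the switch regions and are essentially
invariant across RAS oncoprotein orthologs: residues 31-42 (EYDPTIEDSYRK,
overlapping switch I at 30-40) and residues 59-72 (AGQEEYSAMRDQYM,
overlapping switch II at 58-72).  Related RAS-family paralogs (MRAS, RRAS,
RRAS2) differ at 2-3 positions, so a Hamming scan with a small mismatch
budget discriminates orthologs from their nearest relatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AlignedSet, ProteinRecord, RasevolError


@dataclass(frozen=True)
class SignatureBlock:
    name: str
    expected_start: int  # 1-based residue index in the canonical numbering
    residues: str


BLOCK1 = SignatureBlock("block1", 31, "EYDPTIEDSYRK")
BLOCK2 = SignatureBlock("block2", 59, "AGQEEYSAMRDQYM")
SWITCH_I = (30, 40)
SWITCH_II = (58, 72)
#: switch span each block overlaps, for reporting
_SWITCH_OF_BLOCK = {"block1": SWITCH_I, "block2": SWITCH_II}


@dataclass
class SignatureHit:
    block: str
    start: int        # 1-based position of the match
    mismatches: int
    peptide: str
    offset: int       # start − expected_start


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings; 'X' always mismatches."""
    if len(a) != len(b):
        raise RasevolError(f"hamming: unequal lengths {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "X" or y == "X")


def scan_signature(record: ProteinRecord | str, block: SignatureBlock,
                   max_mismatch: int = 0) -> list[SignatureHit]:
    """Sliding-window Hamming scan of a sequence against a signature block.

    Hits with at most ``max_mismatch`` mismatches, sorted by mismatch count
    then position.
    """
    seq = record.residues if isinstance(record, ProteinRecord) else record
    width = len(block.residues)
    if len(seq) < width:
        raise RasevolError(
            f"sequence shorter ({len(seq)}) than block {block.name!r} ({width})"
        )
    hits = []
    for i in range(len(seq) - width + 1):
        d = hamming(seq[i : i + width], block.residues)
        if d <= max_mismatch:
            start = i + 1
            hits.append(SignatureHit(block=block.name, start=start,
                                     mismatches=d,
                                     peptide=seq[i : i + width],
                                     offset=start - block.expected_start))
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def conserved_blocks(aligned_set: AlignedSet,
                     min_length: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of ≥min_length gap-free, fully identical columns.

    Returns (start_column, end_column) pairs, 0-based inclusive.  A column
    containing any gap can never count as conserved.
    """
    if aligned_set.n_rows < 2:
        raise RasevolError("conserved_blocks requires ≥2 rows")
    arr = np.array([list(row) for row in aligned_set.rows])
    identical = (arr == arr[0]).all(axis=0) & (arr[0] != "-")
    runs = []
    start = None
    for col, ok in enumerate(identical):
        if ok and start is None:
            start = col
        elif not ok and start is not None:
            if col - start >= min_length:
                runs.append((start, col - 1))
            start = None
    if start is not None and len(identical) - start >= min_length:
        runs.append((start, len(identical) - 1))
    return runs


def _overlap(start: int, end: int, span: tuple[int, int]) -> int:
    lo = max(start, span[0])
    hi = min(end, span[1])
    return max(0, hi - lo + 1)


def signature_report(hits_by_record: dict[str, list[SignatureHit]],
                     conserved_runs: list[tuple[int, int]] | None = None
                     ) -> pd.DataFrame:
    """Tabulate signature hits with their switch-region overlap.

    ``switch_overlap`` is the length of the intersection between the hit
    span and the switch region its block overlaps (switch I for block1,
    switch II for block2), in the hit's own coordinates.  Conserved-column
    runs, when given, are appended as ``conserved_run`` rows keyed to all
    records.
    """
    rows = []
    for record_id, hits in hits_by_record.items():
        for h in hits:
            span = _SWITCH_OF_BLOCK.get(h.block)
            overlap = _overlap(h.start, h.start + len(h.peptide) - 1, span) \
                if span else 0
            rows.append({
                "record_id": record_id,
                "block": h.block,
                "position": h.start,
                "mismatches": h.mismatches,
                "matched_peptide": h.peptide,
                "switch_overlap": overlap,
            })
    if conserved_runs:
        for start, end in conserved_runs:
            rows.append({
                "record_id": "<all>",
                "block": "conserved_run",
                "position": start,
                "mismatches": 0,
                "matched_peptide": "",
                "switch_overlap": end - start + 1,
            })
    columns = ["record_id", "block", "position", "mismatches",
               "matched_peptide", "switch_overlap"]
    return pd.DataFrame(rows, columns=columns)
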