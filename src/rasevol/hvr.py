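"""Membrane-anchor (HVR) architecture annotation for RAS-family proteins.

RAS GTPases consist of a conserved catalytic G-domain (residues 1-166) and
a short C-terminal hypervariable region (HVR, ~18-23 residues) that carries
all membrane-targeting information: a terminal CaaX prenylation box, and a
"second signal" that is either palmitoylatable cysteines plus short
polybasic regions (PBR1/PBR2) or a polybasic domain (PBD) with a
neutralized-basic (NB) triplet and a phosphorylation-acceptor S/T.

This module splits a protein into its two domains and annotates the HVR
under those motif grammars:

* CaaX — last four residues ``C a a X``; the terminal residue selects the
  prenyl lipid (L/F → geranylgeranyl, otherwise farnesyl).
* PBR1/PBR2 — ``[KR][hydrophobic][KR][KR]`` tetrapeptides (net charge +3),
  upstream of the first and downstream of the last palmitoyl cysteine
  respectively.
* NB — ``[KR][ED][KR]`` triplet (net charge +1).
* PBD — up to ten residues immediately before the CaaX cysteine containing
  at least four K/R with net charge ≥ +4 (the +8 polylysine stretch of
  KRAS4B is the canonical case).
* phospho acceptor — an S/T three residues upstream of the CaaX cysteine
  (the S181/C185 geometry of human KRAS4B).

Charges use a simple physiological-pH model: +1 for K/R, −1 for D/E, zero
otherwise (histidine treated as neutral).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .io import ProteinRecord, RasevolError

G_DOMAIN_LENGTH = 166

BASIC = set("KR")
ACIDIC = set("DE")
#: Hydrophobic residues admitted at the PBR "hydrophobic" slot.
HYDROPHOBIC = set("AVLIMFWY")
#: Terminal CaaX residues that redirect prenylation to geranylgeranyl.
GERANYLGERANYL_X = set("LF")

PBD_WINDOW = 10
PBD_MIN_BASIC = 4
PBD_MIN_CHARGE = 4

ARCHETYPES = ("KRAS4B-like", "KRASBL-like", "HRAS-like", "NRAS-like",
              "KRAS4A-like", "invertebrate-like", "unclassified")


def net_charge(peptide: str) -> int:
    """Net charge at physiological pH: +1 per K/R, −1 per D/E, 0 otherwise."""
    return sum((aa in BASIC) - (aa in ACIDIC) for aa in peptide)


@dataclass
class CaaXCall:
    """The C-terminal prenylation box of one protein."""

    cys_position: int          # 1-based whole-protein index of the CaaX cysteine
    a1: str
    a2: str
    x: str
    prenyl_type: str | None    # "farnesyl" | "geranylgeranyl" | None
    valid: bool


@dataclass
class MotifHit:
    kind: str                  # PBR1 | PBR2 | NB | PBD
    start: int                 # 1-based inclusive whole-protein coords
    end: int
    peptide: str
    net_charge: int


@dataclass
class HVRProfile:
    """The annotated membrane-anchor architecture of one sequence."""

    record_id: str
    hvr_start: int
    hvr_sequence: str
    caax: CaaXCall | None
    hits: list[MotifHit]
    palmitoyl_cys: list[int]
    phospho_acceptor: int | None
    hvr_net_charge: int
    archetype: str
    valid: bool = True
    notes: list[str] = field(default_factory=list)

    def hit(self, kind: str) -> MotifHit | None:
        for h in self.hits:
            if h.kind == kind:
                return h
        return None


# ---------------------------------------------------------------------------
# Domain split
# ---------------------------------------------------------------------------

def split_domains(record: ProteinRecord,
                  reference: str | None = None) -> tuple[str, str, int]:
    """Split a protein into (G-domain, HVR, hvr_start).

    Default mode cuts after residue 166.  Anchored mode pairwise-aligns the
    record to ``reference`` (a full-length reference protein) and cuts after
    the alignment column holding reference residue 166 — for sequences with
    extended N-/C-termini where absolute numbering does not apply.
    """
    seq = record.residues
    if reference is None:
        if len(seq) < G_DOMAIN_LENGTH:
            raise RasevolError(
                f"record {record.id!r}: length {len(seq)} < {G_DOMAIN_LENGTH}; "
                f"supply a reference for anchored splitting"
            )
        if len(seq) == G_DOMAIN_LENGTH:
            warnings.warn(f"record {record.id!r}: no HVR (length exactly "
                          f"{G_DOMAIN_LENGTH})")
        return seq[:G_DOMAIN_LENGTH], seq[G_DOMAIN_LENGTH:], G_DOMAIN_LENGTH + 1

    from .align import global_align  # local import to avoid cycle at import time

    if len(reference) < G_DOMAIN_LENGTH:
        raise RasevolError("reference shorter than the G-domain (166 residues)")
    aln = global_align(seq, reference)
    # column of reference residue 166
    count = 0
    anchor_col = None
    for col, sym in enumerate(aln.row_b):
        if sym != "-":
            count += 1
            if count == G_DOMAIN_LENGTH:
                anchor_col = col
                break
    assert anchor_col is not None
    if aln.row_a[anchor_col] == "-":
        run = 1
        left = anchor_col - 1
        while left >= 0 and aln.row_a[left] == "-":
            run += 1
            left -= 1
        right = anchor_col + 1
        while right < len(aln.row_a) and aln.row_a[right] == "-":
            run += 1
            right += 1
        if run > 10:
            raise RasevolError(
                f"record {record.id!r}: reference residue {G_DOMAIN_LENGTH} "
                f"aligns inside a {run}-column gap; cannot anchor the split"
            )
    consumed = sum(1 for sym in aln.row_a[: anchor_col + 1] if sym != "-")
    return seq[:consumed], seq[consumed:], consumed + 1


# ---------------------------------------------------------------------------
# CaaX classification
# ---------------------------------------------------------------------------

def classify_caax(hvr_segment: str, hvr_start: int) -> CaaXCall:
    """Classify the terminal CaaX box of an HVR segment.

    Valid iff the fourth-from-last residue is C.  The terminal residue
    selects the prenyl lipid: L or F → geranylgeranyl, anything else →
    farnesyl.  Positions are reported in whole-protein coordinates.
    """
    if len(hvr_segment) < 4:
        raise RasevolError("HVR segment shorter than 4 residues; no CaaX call")
    c, a1, a2, x = hvr_segment[-4:]
    valid = c == "C"
    prenyl = None
    if valid:
        prenyl = "geranylgeranyl" if x in GERANYLGERANYL_X else "farnesyl"
    cys_position = hvr_start + len(hvr_segment) - 4
    return CaaXCall(cys_position=cys_position, a1=a1, a2=a2, x=x,
                    prenyl_type=prenyl, valid=valid)


# ---------------------------------------------------------------------------
# Motif detection
# ---------------------------------------------------------------------------

def _is_pbr(tetramer: str) -> bool:
    return (len(tetramer) == 4 and tetramer[0] in BASIC
            and tetramer[1] in HYDROPHOBIC
            and tetramer[2] in BASIC and tetramer[3] in BASIC)


def _is_nb(trimer: str) -> bool:
    return (len(trimer) == 3 and trimer[0] in BASIC
            and trimer[1] in ACIDIC and trimer[2] in BASIC)


def _leftmost(segment: str, lo: int, hi: int, width: int, pred) -> int | None:
    """Leftmost start index i in [lo, hi-width] with pred(segment[i:i+width])."""
    for i in range(max(lo, 0), hi - width + 1):
        if pred(segment[i : i + width]):
            return i
    return None


def find_palmitoyl_cysteines(hvr_segment: str, hvr_start: int,
                             caax: CaaXCall | None) -> list[int]:
    """All HVR cysteines excluding the CaaX cysteine (whole-protein coords)."""
    excluded = caax.cys_position if caax is not None and caax.valid else None
    positions = []
    for i, aa in enumerate(hvr_segment):
        pos = hvr_start + i
        if aa == "C" and pos != excluded:
            positions.append(pos)
    return positions


def detect_motifs(hvr_segment: str, hvr_start: int, caax: CaaXCall,
                  palmitoyl_cys: list[int]) -> list[MotifHit]:
    """Detect PBD, NB, PBR1 and PBR2 motifs in an HVR segment.

    Leftmost match wins within each search region.  An invalid CaaX call
    blocks the PBD and PBR2 (both are defined relative to the CaaX
    cysteine); PBR1 and NB are still searched.
    """
    hits: list[MotifHit] = []
    n = len(hvr_segment)
    cys_local = caax.cys_position - hvr_start if caax.valid else None
    palm_local = [p - hvr_start for p in palmitoyl_cys]

    def emit(kind: str, start_local: int, end_local: int) -> MotifHit:
        peptide = hvr_segment[start_local : end_local + 1]
        hit = MotifHit(kind=kind, start=hvr_start + start_local,
                       end=hvr_start + end_local, peptide=peptide,
                       net_charge=net_charge(peptide))
        hits.append(hit)
        return hit

    # PBD: ≤10-residue window ending immediately before the CaaX cysteine,
    # left-trimmed of non-basic residues; requires ≥4 K/R and charge ≥ +4.
    pbd_start_local: int | None = None
    if cys_local is None:
        warnings.warn("invalid CaaX: PBD and PBR2 not searched")
    else:
        w_start = max(0, cys_local - PBD_WINDOW)
        window = hvr_segment[w_start:cys_local]
        trim = 0
        while trim < len(window) and window[trim] not in BASIC:
            trim += 1
        trimmed = window[trim:]
        if (sum(aa in BASIC for aa in trimmed) >= PBD_MIN_BASIC
                and net_charge(trimmed) >= PBD_MIN_CHARGE):
            pbd_start_local = w_start + trim
            emit("PBD", pbd_start_local, cys_local - 1)

    # NB: [KR][ED][KR] upstream of the PBD (or of the first palmitoyl
    # cysteine / CaaX cysteine when no PBD is present).
    if pbd_start_local is not None:
        nb_bound = pbd_start_local
    elif palm_local:
        nb_bound = min(palm_local)
    elif cys_local is not None:
        nb_bound = cys_local
    else:
        nb_bound = n
    i = _leftmost(hvr_segment, 0, nb_bound, 3, _is_nb)
    if i is not None:
        emit("NB", i, i + 2)

    # PBR1: strictly upstream of the first palmitoyl cysteine; in sequences
    # without palmitoyl cysteines, upstream of the PBD/CaaX instead.
    if palm_local:
        pbr1_bound = min(palm_local)
    elif pbd_start_local is not None:
        pbr1_bound = pbd_start_local
    elif cys_local is not None:
        pbr1_bound = cys_local
    else:
        pbr1_bound = n
    i = _leftmost(hvr_segment, 0, pbr1_bound, 4, _is_pbr)
    if i is not None:
        emit("PBR1", i, i + 3)

    # PBR2: strictly between the last palmitoyl cysteine and the CaaX cysteine.
    if palm_local and cys_local is not None:
        i = _leftmost(hvr_segment, max(palm_local) + 1, cys_local, 4, _is_pbr)
        if i is not None:
            emit("PBR2", i, i + 3)

    return hits


def detect_phospho_acceptor(hvr_segment: str, hvr_start: int,
                            caax: CaaXCall) -> int | None:
    """S/T acceptor three residues upstream of the CaaX cysteine (c−4)."""
    if not caax.valid:
        return None
    local = caax.cys_position - hvr_start - 4
    if local < 0:
        return None
    if hvr_segment[local] in "ST":
        return hvr_start + local
    return None


# ---------------------------------------------------------------------------
# Profile + archetype
# ---------------------------------------------------------------------------

def profile_hvr(record: ProteinRecord,
                reference: str | None = None) -> HVRProfile:
    """Full membrane-anchor annotation of one protein.

    Sub-operation failures (too-short sequence, no CaaX window) yield a
    profile flagged ``valid=False`` instead of aborting a batch run.
    """
    try:
        _, hvr_seq, hvr_start = split_domains(record, reference)
        caax = classify_caax(hvr_seq, hvr_start) if len(hvr_seq) >= 4 else None
    except RasevolError as exc:
        return HVRProfile(record_id=record.id, hvr_start=0, hvr_sequence="",
                          caax=None, hits=[], palmitoyl_cys=[],
                          phospho_acceptor=None, hvr_net_charge=0,
                          archetype="unclassified", valid=False,
                          notes=[str(exc)])
    palmitoyl = find_palmitoyl_cysteines(hvr_seq, hvr_start, caax)
    notes: list[str] = []
    if caax is None:
        hits: list[MotifHit] = []
        phospho = None
        notes.append("HVR too short for a CaaX call")
    else:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            hits = detect_motifs(hvr_seq, hvr_start, caax, palmitoyl)
        notes.extend(str(w.message) for w in caught)
        phospho = detect_phospho_acceptor(hvr_seq, hvr_start, caax)
    profile = HVRProfile(
        record_id=record.id, hvr_start=hvr_start, hvr_sequence=hvr_seq,
        caax=caax, hits=hits, palmitoyl_cys=palmitoyl,
        phospho_acceptor=phospho, hvr_net_charge=net_charge(hvr_seq),
        archetype="unclassified",
        valid=caax is not None and caax.valid, notes=notes,
    )
    profile.archetype = classify_archetype(profile, record.clade_label)
    return profile


def classify_archetype(profile: HVRProfile,
                       clade_label: str | None = None) -> str:
    """Assign an HVR architecture archetype from a motif profile.

    Decision table (first matching rule wins):

    1. PBD ∧ NB ∧ phospho-acceptor ∧ no palmitoyl cysteines —
       farnesyl → KRAS4B-like; geranylgeranyl → KRASBL-like for vertebrate
       clades, invertebrate-like otherwise.
    2. PBR1 ∧ two palmitoyl cysteines → HRAS-like.
    3. PBR1 ∧ one palmitoyl cysteine ∧ PBR2 → KRAS4A-like.
    4. PBR1 ∧ one palmitoyl cysteine ∧ no PBR2 → NRAS-like.
    5. otherwise → unclassified.
    """
    caax = profile.caax
    if caax is None or not caax.valid:
        return "unclassified"
    pbd = profile.hit("PBD") is not None
    nb = profile.hit("NB") is not None
    pbr1 = profile.hit("PBR1") is not None
    pbr2 = profile.hit("PBR2") is not None
    n_palm = len(profile.palmitoyl_cys)
    if pbd and nb and profile.phospho_acceptor is not None and n_palm == 0:
        if pbd and pbr1:
            profile.notes.append("both PBD and PBR1 present; PBD rule takes precedence")
        if caax.prenyl_type == "farnesyl":
            return "KRAS4B-like"
        if clade_label is not None and clade_label.lower() == "vertebrate":
            return "KRASBL-like"
        return "invertebrate-like"
    if pbr1 and n_palm == 2:
        return "HRAS-like"
    if pbr1 and n_palm == 1 and pbr2:
        return "KRAS4A-like"
    if pbr1 and n_palm == 1:
        return "NRAS-like"
    return "unclassified"


# ---------------------------------------------------------------------------
# Batch table
# ---------------------------------------------------------------------------

def motif_table(records: list[ProteinRecord],
                reference: str | None = None) -> pd.DataFrame:
    """Per-sequence motif annotation table (one row per record)."""
    rows = []
    for rec in records:
        p = profile_hvr(rec, reference)
        caax = p.caax

        def pep(kind: str) -> str:
            h = p.hit(kind)
            return h.peptide if h else ""

        pbd = p.hit("PBD")
        rows.append({
            "record_id": rec.id,
            "species": rec.species,
            "clade": rec.clade_label or "",
            "archetype": p.archetype,
            "caax_peptide": p.hvr_sequence[-4:] if len(p.hvr_sequence) >= 4 else "",
            "prenyl_type": caax.prenyl_type if caax and caax.valid else "",
            "pbr1": pep("PBR1"),
            "pbr2": pep("PBR2"),
            "nb": pep("NB"),
            "pbd": pbd.peptide if pbd else "",
            "pbd_charge": pbd.net_charge if pbd else "",
            "palmitoyl_positions": ",".join(map(str, p.palmitoyl_cys)),
            "phospho_position": p.phospho_acceptor if p.phospho_acceptor else "",
            "hvr_charge": p.hvr_net_charge,
        })
    return pd.DataFrame(rows)
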