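"""Global protein alignment, percent identity, and a small progressive MSA.

The aligner is a Gotoh affine-gap Needleman-Wunsch with BLAST-style gap
costs: a gap of length k costs ``gap_open + k * gap_extend`` (defaults
11/1, matching BLASTP).  Traceback tie-breaking is fixed — prefer a
match/mismatch step over a gap, then a gap in sequence a over a gap in
sequence b — so alignments are fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import GAP, AlignedSet, ProteinRecord, RasevolError

NEG_INF = float("-inf")

_MATRIX_CACHE: dict[str, dict[tuple[str, str], float]] = {}


def load_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """Load a substitution matrix as a symbol-pair score lookup."""
    if name not in _MATRIX_CACHE:
        try:
            mat = substitution_matrices.load(name)
        except FileNotFoundError:
            raise RasevolError(f"unknown substitution matrix {name!r}") from None
        table: dict[tuple[str, str], float] = {}
        for a in mat.alphabet:
            for b in mat.alphabet:
                table[(a, b)] = float(mat[a, b])
        _MATRIX_CACHE[name] = table
    return _MATRIX_CACHE[name]


@dataclass
class PairwiseAlignment:
    """A gapped global alignment of two sequences."""

    row_a: str
    row_b: str
    score: float
    identities: int
    columns: int

    def __post_init__(self) -> None:
        assert len(self.row_a) == len(self.row_b) == self.columns
        assert self.identities <= self.columns


def _score_lookup(table, a: str, b: str) -> float:
    try:
        return table[(a, b)]
    except KeyError:
        # symbols absent from the matrix (rare) score as the X row
        return table.get((a, "X"), table.get(("X", b), -1.0))


def global_align(a: str, b: str, matrix_name: str = "BLOSUM62",
                 gap_open: float = 11.0, gap_extend: float = 1.0
                 ) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences with affine gaps.

    Gap cost for a run of length k is ``gap_open + k*gap_extend``.
    """
    if not a or not b:
        raise RasevolError("global_align requires non-empty sequences")
    if gap_open <= 0 or gap_extend <= 0:
        raise RasevolError("gap penalties must be positive")
    table = load_matrix(matrix_name)
    n, m = len(a), len(b)
    # M: a[i] aligned to b[j]; X: gap in a (consuming b); Y: gap in b
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        Y[i, 0] = -(gap_open + i * gap_extend)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = _score_lookup(table, ai, b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i, j - 1] - gap_open - gap_extend,
                          X[i, j - 1] - gap_extend,
                          Y[i, j - 1] - gap_open - gap_extend)
            Y[i, j] = max(M[i - 1, j] - gap_open - gap_extend,
                          Y[i - 1, j] - gap_extend,
                          X[i - 1, j] - gap_open - gap_extend)
    # traceback; preference order: M (match/mismatch), X (gap in a), Y (gap in b)
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][n, m])
    for st in ("M", "X", "Y"):  # deterministic tie-break by preference order
        if {"M": M, "X": X, "Y": Y}[st][n, m] == {"M": M, "X": X, "Y": Y}[state][n, m]:
            state = st
            break
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = _score_lookup(table, a[i - 1], b[j - 1])
            target = M[i, j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if np.isclose(mat[i, j], target):
                    state = st
                    break
        elif state == "X":
            target = X[i, j]
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
            if np.isclose(M[i, j] - gap_open - gap_extend, target):
                state = "M"
            elif np.isclose(X[i, j] - gap_extend, target):
                state = "X"
            else:
                state = "Y"
        else:
            target = Y[i, j]
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            if np.isclose(M[i, j] - gap_open - gap_extend, target):
                state = "M"
            elif np.isclose(Y[i, j] - gap_extend, target):
                state = "Y"
            else:
                state = "X"
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "X"
        elif j == 0:
            state = "Y"
    row_a = "".join(reversed(out_a))
    row_b = "".join(reversed(out_b))
    identities = sum(1 for x, y in zip(row_a, row_b) if x == y and x != GAP)
    score = float(max(M[n, m], X[n, m], Y[n, m]))
    return PairwiseAlignment(row_a=row_a, row_b=row_b, score=score,
                             identities=identities, columns=len(row_a))


def percent_identity(aln: PairwiseAlignment, denominator: str = "columns") -> float:
    """Percent identity of a pairwise alignment, to one decimal.

    ``denominator="columns"`` (default) divides by all alignment columns,
    gap columns included — the BLAST "Identities = n/m" convention.
    ``denominator="ungapped"`` divides by gap-free columns only.
    """
    if aln.columns == 0:
        raise RasevolError("alignment has zero columns")
    if denominator == "columns":
        denom = aln.columns
    elif denominator == "ungapped":
        denom = sum(1 for x, y in zip(aln.row_a, aln.row_b)
                    if x != GAP and y != GAP)
        if denom == 0:
            raise RasevolError("alignment has no ungapped columns")
    else:
        raise RasevolError(f"unknown denominator {denominator!r}")
    return round(100.0 * aln.identities / denom, 1)


def identity_matrix(records: list[ProteinRecord],
                    references: list[ProteinRecord],
                    matrix_name: str = "BLOSUM62",
                    gap_open: float = 11.0, gap_extend: float = 1.0,
                    denominator: str = "columns") -> pd.DataFrame:
    """Records × references percent-identity table (rows=records)."""
    if not records or not references:
        raise RasevolError("identity_matrix needs ≥1 record and ≥1 reference")
    data = {}
    for ref in references:
        col = []
        for rec in records:
            try:
                aln = global_align(rec.residues, ref.residues, matrix_name,
                                   gap_open, gap_extend)
                col.append(percent_identity(aln, denominator))
            except RasevolError as exc:
                warnings.warn(f"identity {rec.id} vs {ref.id} failed: {exc}")
                col.append(float("nan"))
        data[ref.id] = col
    return pd.DataFrame(data, index=[rec.id for rec in records])


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------

def _profile_column_score(col_a: list[str], col_b: list[str], table) -> float:
    """Mean substitution score over residue pairs; gap pairs contribute 0."""
    total, pairs = 0.0, 0
    for x in col_a:
        for y in col_b:
            pairs += 1
            if x != GAP and y != GAP:
                total += _score_lookup(table, x, y)
    return total / pairs if pairs else 0.0


def _profile_align(rows_a: list[str], rows_b: list[str], table,
                   gap_open: float, gap_extend: float
                   ) -> tuple[list[str], list[str]]:
    """Gotoh alignment of two profiles (lists of equal-length gapped rows)."""
    n = len(rows_a[0])
    m = len(rows_b[0])
    cols_a = [[row[i] for row in rows_a] for i in range(n)]
    cols_b = [[row[j] for row in rows_b] for j in range(m)]
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        Y[i, 0] = -(gap_open + i * gap_extend)
    S = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            S[i, j] = _profile_column_score(cols_a[i], cols_b[j], table)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + S[i - 1, j - 1]
            X[i, j] = max(M[i, j - 1] - gap_open - gap_extend,
                          X[i, j - 1] - gap_extend,
                          Y[i, j - 1] - gap_open - gap_extend)
            Y[i, j] = max(M[i - 1, j] - gap_open - gap_extend,
                          Y[i - 1, j] - gap_extend,
                          X[i - 1, j] - gap_open - gap_extend)
    i, j = n, m
    mats = {"M": M, "X": X, "Y": Y}
    state = "M"
    best = max(mats.values(), key=lambda mat: mat[n, m])[n, m]
    for st in ("M", "X", "Y"):
        if mats[st][n, m] == best:
            state = st
            break
    steps: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            target = M[i, j] - S[i - 1, j - 1]
            steps.append("M")
            i, j = i - 1, j - 1
            for st in ("M", "X", "Y"):
                if np.isclose(mats[st][i, j], target):
                    state = st
                    break
        elif state == "X":
            target = X[i, j]
            steps.append("X")
            j -= 1
            if np.isclose(M[i, j] - gap_open - gap_extend, target):
                state = "M"
            elif np.isclose(X[i, j] - gap_extend, target):
                state = "X"
            else:
                state = "Y"
        else:
            target = Y[i, j]
            steps.append("Y")
            i -= 1
            if np.isclose(M[i, j] - gap_open - gap_extend, target):
                state = "M"
            elif np.isclose(Y[i, j] - gap_extend, target):
                state = "Y"
            else:
                state = "X"
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "X"
        elif j == 0:
            state = "Y"
    steps.reverse()
    new_a = ["" for _ in rows_a]
    new_b = ["" for _ in rows_b]
    ia = ib = 0
    for step in steps:
        if step == "M":
            for k, row in enumerate(rows_a):
                new_a[k] += row[ia]
            for k, row in enumerate(rows_b):
                new_b[k] += row[ib]
            ia += 1
            ib += 1
        elif step == "X":
            for k in range(len(rows_a)):
                new_a[k] += GAP
            for k, row in enumerate(rows_b):
                new_b[k] += row[ib]
            ib += 1
        else:
            for k, row in enumerate(rows_a):
                new_a[k] += row[ia]
            for k in range(len(rows_b)):
                new_b[k] += GAP
            ia += 1
    return new_a, new_b


def progressive_msa(records: list[ProteinRecord],
                    matrix_name: str = "BLOSUM62",
                    gap_open: float = 11.0, gap_extend: float = 1.0
                    ) -> AlignedSet:
    """Progressive multiple alignment for near-identical families.

    The guide order comes from single-linkage clustering of pairwise
    p-distances (mismatch fraction of the pairwise global alignment);
    profiles are merged with profile-to-profile Gotoh alignment under the
    same scoring.  Deterministic.  For divergent sets an external aligner
    should be preferred.
    """
    if len(records) < 2:
        raise RasevolError("progressive_msa requires ≥2 records")
    table = load_matrix(matrix_name)
    n = len(records)
    if n == 2:
        aln = global_align(records[0].residues, records[1].residues,
                           matrix_name, gap_open, gap_extend)
        return AlignedSet([records[0].id, records[1].id], [aln.row_a, aln.row_b])
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i].residues, records[j].residues,
                               matrix_name, gap_open, gap_extend)
            dist[i, j] = dist[j, i] = 1.0 - aln.identities / aln.columns
    Z = hierarchy.linkage(squareform(dist, checks=False), method="single")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].residues]) for i in range(n)
    }
    next_id = n
    for a_id, b_id, _, _ in Z:
        ids_a, rows_a = clusters.pop(int(a_id))
        ids_b, rows_b = clusters.pop(int(b_id))
        new_a, new_b = _profile_align(rows_a, rows_b, table, gap_open, gap_extend)
        clusters[next_id] = (ids_a + ids_b, new_a + new_b)
        next_id += 1
    (ids, rows), = clusters.values()
    # restore input order
    order = sorted(range(len(ids)), key=lambda k: ids[k])
    return AlignedSet([records[ids[k]].id for k in order],
                      [rows[k] for k in order])
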