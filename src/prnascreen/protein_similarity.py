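"""Motor-component co-occurrence checks by exact local protein alignment.

A genuine packaging-motor pRNA should come from a genome that also encodes
the two protein components of the motor: the connector/channel protein
(gp10 in phi29) and the packaging ATPase (gp16). The check aligns each
supplied CDS translation against each reference protein with an exact
Smith–Waterman–Gotoh local alignment (BLOSUM62, affine gap existence 11 /
extension 1 — the standard protein-search parameters) and reports the
best hit's query coverage and percent identity. Exact alignment replaces a
heuristic database search deliberately: presence/similarity of two named
proteins in a small CDS set is answered optimally and deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .io_formats import PROTEIN_ALPHABET, SeqRecord

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class LocalAlignment:
    """An optimal local alignment between a query and a subject protein.

    Spans are 0-based half-open; aligned strings include ``-`` gap
    characters and have equal length. ``score`` is the raw substitution +
    affine-gap score (0 for the empty alignment).
    """

    query_id: str
    subject_id: str
    qs: int
    qe: int
    ss: int
    se: int
    aligned_query: str
    aligned_subject: str
    score: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    @property
    def n_identical(self) -> int:
        return sum(a == b != "-" for a, b in zip(self.aligned_query, self.aligned_subject))


def _validate_protein(rec: SeqRecord) -> str:
    bad = set(rec.residues) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"non-protein character(s) {sorted(bad)} in {rec.id!r}")
    return rec.residues


def substitution_score(a: str, b: str, matrix=None) -> float:
    m = _BLOSUM62 if matrix is None else matrix
    return float(m[a][b])


def local_align(
    query: SeqRecord,
    subject: SeqRecord,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> LocalAlignment:
    """Optimal Smith–Waterman local alignment with affine gaps (Gotoh).

    A gap of length k costs ``gap_open + k * gap_extend``. The traceback is
    deterministic: the best cell with the smallest (query, subject) indices
    wins, and ties within a cell prefer the diagonal, then a gap in the
    subject (up), then a gap in the query (left).
    """
    q = _validate_protein(query)
    s = _validate_protein(subject)
    m = _BLOSUM62 if matrix is None else matrix
    n, mm = len(q), len(s)
    neg = -np.inf
    H = np.zeros((n + 1, mm + 1))
    E = np.full((n + 1, mm + 1), neg)  # gap in query (left moves)
    F = np.full((n + 1, mm + 1), neg)  # gap in subject (up moves)
    first_open = gap_open + gap_extend  # first gapped residue
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        row_scores = [float(m[qi][s[j - 1]]) for j in range(1, mm + 1)]
        for j in range(1, mm + 1):
            E[i, j] = max(H[i, j - 1] - first_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - first_open, F[i - 1, j] - gap_extend)
            h = max(0.0, H[i - 1, j - 1] + row_scores[j - 1], F[i, j], E[i, j])
            H[i, j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return LocalAlignment(query.id, subject.id, 0, 0, 0, 0, "", "", 0.0)

    # traceback from (bi, bj), preferring diagonal, then up (F), then left (E)
    aq: list[str] = []
    asub: list[str] = []
    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + float(m[q[i - 1]][s[j - 1]])
            if H[i, j] == diag:
                aq.append(q[i - 1])
                asub.append(s[j - 1])
                i, j = i - 1, j - 1
                continue
            if H[i, j] == F[i, j]:
                state = "F"
                continue
            state = "E"
            continue
        if state == "F":
            aq.append(q[i - 1])
            asub.append("-")
            closed = F[i, j] == H[i - 1, j] - first_open
            i -= 1
            state = "H" if closed else "F"
            continue
        # state == "E"
        aq.append("-")
        asub.append(s[j - 1])
        closed = E[i, j] == H[i, j - 1] - first_open
        j -= 1
        state = "H" if closed else "E"
    return LocalAlignment(
        query_id=query.id,
        subject_id=subject.id,
        qs=i,
        qe=bi,
        ss=j,
        se=bj,
        aligned_query="".join(reversed(aq)),
        aligned_subject="".join(reversed(asub)),
        score=float(best),
    )


def query_coverage(a: LocalAlignment, query_len: int) -> float:
    """Percent of the query included in the aligned span."""
    if a.qe > query_len:
        raise ValueError("alignment extends past the query length")
    return 100.0 * (a.qe - a.qs) / query_len


def percent_identity(a: LocalAlignment, denominator: str = "alignment") -> float:
    """Percent identical columns.

    ``denominator="alignment"`` counts all alignment columns including gap
    columns; ``denominator="reference"`` divides by the query span instead
    (both conventions are in circulation; alignment columns is the default).
    """
    if a.n_columns == 0:
        import logging

        logging.getLogger(__name__).warning("percent identity of an empty alignment is 0")
        return 0.0
    if denominator == "alignment":
        return 100.0 * a.n_identical / a.n_columns
    if denominator == "reference":
        return 100.0 * a.n_identical / (a.qe - a.qs)
    raise ValueError("denominator must be 'alignment' or 'reference'")


@dataclass(frozen=True)
class MotorCheckReport:
    """Best hit per reference protein plus the overall pass flag."""

    table: pd.DataFrame
    passed: bool


def motor_component_check(
    genome_cds: list[SeqRecord],
    references: list[SeqRecord],
    min_coverage: float = 50.0,
    min_identity: float = 25.0,
    identity_denominator: str = "alignment",
) -> MotorCheckReport:
    """Do the CDS translations contain homologs of every reference protein?

    The best-scoring CDS is reported per reference; the check passes iff
    every reference's best hit meets both the coverage and identity
    thresholds. An empty CDS list fails with an empty table row per
    reference.
    """
    if not references:
        raise ValueError("at least one reference protein is required")
    rows = []
    all_pass = True
    for ref in references:
        best: LocalAlignment | None = None
        for cds in genome_cds:
            a = local_align(ref, cds)
            if best is None or a.score > best.score:
                best = a
        if best is None or best.n_columns == 0:
            rows.append(
                {
                    "reference": ref.id,
                    "best_cds": None,
                    "score": 0.0,
                    "query_coverage": 0.0,
                    "percent_identity": 0.0,
                    "pass": False,
                }
            )
            all_pass = False
            continue
        cov = query_coverage(best, len(ref.residues))
        ident = percent_identity(best, denominator=identity_denominator)
        ok = cov >= min_coverage and ident >= min_identity
        all_pass = all_pass and ok
        rows.append(
            {
                "reference": ref.id,
                "best_cds": best.subject_id,
                "score": best.score,
                "query_coverage": round(cov, 2),
                "percent_identity": round(ident, 2),
                "pass": ok,
            }
        )
    return MotorCheckReport(table=pd.DataFrame(rows), passed=all_pass)
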