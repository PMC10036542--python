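"""Homology-based transcription-factor screening.

Candidate strain proteins are aligned to a reference database of known
prokaryotic TFs with exact local (Smith-Waterman) alignment under BLOSUM62
and affine gap penalties, and kept when the best hit clears an e-value
threshold (default 0.05).  The best-scoring reference TF of each surviving
protein becomes its PWM donor for the downstream motif-transfer step.

The e-value follows the Karlin-Altschul form E = K * m * n * exp(-lambda*S)
with fixed gapped-BLOSUM62 constants (lambda = 0.267, K = 0.041, the
standard pair for gap open 11 / extend 1); n is the total residue count of
the database.  A gap of length k is penalized open + k * extend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class KarlinParams:
    """Statistical and scoring parameters for the local-alignment screen."""

    lam: float = 0.267
    K: float = 0.041
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    subject: str
    score: int
    evalue: float
    identity: float

    def __post_init__(self) -> None:
        if self.score < 0 or self.evalue <= 0 or not 0 <= self.identity <= 1:
            raise ValueError("invalid alignment hit")


def _validate_protein(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty protein sequence")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"{label}: unknown residues {sorted(bad)}")


def _make_aligner(params: KarlinParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # first gap position costs open+extend, each further position extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def smith_waterman(
    query: str,
    subject: str,
    params: KarlinParams = KarlinParams(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Exact local alignment of two proteins; returns score and identity.

    The score is the maximal Smith-Waterman score under the configured
    substitution matrix and affine gap model; identity is the fraction of
    identical columns over the local alignment's length (gap columns
    included in the denominator).
    """
    _validate_protein(query, query_id)
    _validate_protein(subject, subject_id)
    aligner = _make_aligner(params)
    score = int(round(aligner.score(query, subject)))
    if score <= 0:
        # no positive-scoring local alignment exists
        e = evalue(0, len(query), len(subject), params)
        return AlignmentHit(query_id, subject_id, 0, e, 0.0)
    best = aligner.align(query, subject)[0]
    counts = best.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aln_len if aln_len else 0.0
    e = evalue(score, len(query), len(subject), params)
    return AlignmentHit(query_id, subject_id, score, e, identity)


def local_score(query: str, subject: str, params: KarlinParams = KarlinParams()) -> int:
    """Smith-Waterman score only (no traceback) — used for all-vs-all scans."""
    _validate_protein(query, "query")
    _validate_protein(subject, "subject")
    return int(round(_make_aligner(params).score(query, subject)))


def evalue(score: float, m: int, n: int, params: KarlinParams = KarlinParams()) -> float:
    """Karlin-Altschul expected number of chance hits at or above `score`."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence/database lengths must be positive")
    return params.K * m * n * math.exp(-params.lam * score)


def screen_tfs(
    proteome: Mapping[str, str],
    tfdb: Mapping[str, str],
    e_threshold: float = 0.05,
    candidates: Optional[set[str]] = None,
    params: KarlinParams = KarlinParams(),
) -> dict[str, AlignmentHit]:
    """Select putative TFs by best-hit e-value against the reference TF set.

    If `candidates` is given (e.g. from an external TF predictor) only those
    proteins are screened; otherwise the whole proteome is.  A protein
    passes iff its best reference hit has E < e_threshold; ties on score are
    broken by smaller e-value, then lexicographic subject id.  The winning
    subject is the protein's PWM donor.
    """
    if not tfdb:
        raise ValueError("reference TF database is empty")
    db_len = sum(len(s) for s in tfdb.values())
    aligner = _make_aligner(params)
    queries = proteome if candidates is None else {
        q: s for q, s in proteome.items() if q in candidates
    }
    result: dict[str, AlignmentHit] = {}
    for qid, qseq in queries.items():
        _validate_protein(qseq, qid)
        best: tuple | None = None
        for sid in sorted(tfdb):
            sseq = tfdb[sid]
            s = int(round(aligner.score(qseq, sseq)))
            e = evalue(s, len(qseq), db_len, params)
            key = (-s, e, sid)
            if best is None or key < best[0]:
                best = (key, sid, s, e)
        assert best is not None
        _, sid, s, e = best
        if e < e_threshold:
            hit = smith_waterman(qseq, tfdb[sid], params, qid, sid)
            # recompute e-value against database length, not subject length
            result[qid] = AlignmentHit(qid, sid, hit.score, e, hit.identity)
    return result
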