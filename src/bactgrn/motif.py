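"""PWM transfer and log-odds genome scanning.

Each screened strain TF inherits the position probability matrix of its
most similar reference TF.  The genome is scanned exhaustively on both
strands with the background-corrected log-odds form of the matrix; windows
scoring at least `threshold_frac` of the maximum attainable score are
emitted as binding sites.  Minus-strand matches are scored on the reverse
complement and reported in plus-strand coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .homology import AlignmentHit
from .io import NUCLEOTIDES

_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over (A, C, G, T), shape 4 x L."""

    tf_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x L")
        if (m < 0).any() or not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must be probabilities summing to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(NUCLEOTIDES[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True, order=True)
class BindingSite:
    """A scored motif match; 0-based half-open plus-strand coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    tf_id: str
    score: float


def transfer_pwm(
    screen: Mapping[str, AlignmentHit], tfdb_pwms: Mapping[str, np.ndarray]
) -> dict[str, PWM]:
    """Assign each screened strain TF an exact copy of its donor's PWM."""
    out: dict[str, PWM] = {}
    for tf_id, hit in screen.items():
        if hit.subject not in tfdb_pwms:
            raise KeyError(f"no PWM for donor {hit.subject!r} of {tf_id!r}")
        out[tf_id] = PWM(tf_id, np.array(tfdb_pwms[hit.subject], dtype=float))
    return out


def pwm_log_odds(
    pwm: PWM,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.01,
) -> np.ndarray:
    """Background-corrected log-odds matrix in bits.

    entry(b, j) = log2( (p(b,j) + pseudocount*q(b)) / ((1+pseudocount)*q(b)) )
    """
    q = np.asarray(background, dtype=float)
    if q.shape != (4,) or not np.isclose(q.sum(), 1.0) or (q <= 0).any():
        raise ValueError("background must be 4 strictly positive probs summing to 1")
    p = pwm.matrix
    return np.log2((p + pseudocount * q[:, None]) / ((1 + pseudocount) * q[:, None]))


def max_score(log_odds: np.ndarray) -> float:
    """Best attainable window score: sum of column maxima."""
    return float(log_odds.max(axis=0).sum())


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; ambiguous bases -> 4 (scores as 0 per position)."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return arr


def _window_scores(log_odds: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Score every window of length L; exhaustive, vectorized over positions."""
    L = log_odds.shape[1]
    n = encoded.size - L + 1
    if n <= 0:
        return np.zeros(0)
    # row of zeros for ambiguous bases: background-expected contribution
    table = np.vstack([log_odds, np.zeros((1, L))])
    scores = np.zeros(n)
    for j in range(L):
        scores += table[encoded[j:j + n], j]
    return scores


def scan_genome(
    log_odds: np.ndarray,
    genome: Mapping[str, str],
    tf_id: str,
    threshold_frac: float = 0.8,
) -> list[BindingSite]:
    """Emit every window on either strand scoring >= threshold_frac * max.

    Sites from the minus strand are scored on the reverse complement but
    reported with plus-strand coordinates.  Output is sorted by
    (contig, start, strand, tf) — a deterministic ordering contract.
    """
    L = log_odds.shape[1]
    cutoff = threshold_frac * max_score(log_odds)
    sites: list[BindingSite] = []
    for contig, seq in genome.items():
        if len(seq) < L:
            continue
        fwd = _encode(seq.upper())
        for strand, enc in (("+", fwd), ("-", _encode(reverse_complement(seq.upper())))):
            scores = _window_scores(log_odds, enc)
            for pos in np.flatnonzero(scores >= cutoff):
                if strand == "+":
                    start = int(pos)
                else:
                    start = len(seq) - int(pos) - L
                sites.append(
                    BindingSite(contig, start, start + L, strand, tf_id, float(scores[pos]))
                )
    sites.sort(key=lambda s: (s.contig, s.start, s.strand, s.tf_id))
    return sites


def scan_all(
    pwms: Mapping[str, PWM],
    genome: Mapping[str, str],
    threshold_frac: float = 0.8,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.01,
) -> list[BindingSite]:
    """Scan the genome with every transferred PWM; concatenated sorted output."""
    sites: list[BindingSite] = []
    for tf_id in sorted(pwms):
        lo = pwm_log_odds(pwms[tf_id], background, pseudocount)
        sites.extend(scan_genome(lo, genome, tf_id, threshold_frac))
    sites.sort(key=lambda s: (s.contig, s.start, s.strand, s.tf_id))
    return sites


def write_sites_bed(path, sites: Sequence[BindingSite]) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.tf_id}\t{s.score:.4f}\t{s.strand}\n")


def read_sites_bed(path) -> list[BindingSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, tf, score, strand = line.split()[:6]
            sites.append(BindingSite(c, int(s), int(e), strand, tf, float(score)))
    return sites
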