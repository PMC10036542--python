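"""Independent reference implementations used only to check the package.

These deliberately use naive formulations (explicit DP tables, window
loops, combinatorial sums, dense linear solves, subset enumeration) so they
share no code path with the implementations they verify.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Naive affine-gap local alignment DP (Gotoh three-state recurrence).

    A gap of length k costs gap_open + k * gap_extend.
    """
    first = gap_open + gap_extend
    m, n = len(a), len(b)
    NEG = -10**9
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (consume b)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (consume a)
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + int(_BLOSUM62[a[i - 1], b[j - 1]])
            H[i][j] = max(0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def brute_force_scan(log_odds: np.ndarray, seq: str, threshold_frac: float):
    """Window-by-window scan of both strands with explicit python loops.

    Returns a set of (start, strand, rounded score) in plus coordinates.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = log_odds.shape[1]
    cutoff = threshold_frac * sum(max(log_odds[b, j] for b in range(4)) for j in range(L))
    hits = set()
    for start in range(len(seq) - L + 1):
        window = seq[start:start + L]
        s_fwd = sum(log_odds[idx[c], j] for j, c in enumerate(window))
        if s_fwd >= cutoff:
            hits.add((start, "+", round(s_fwd, 6)))
        rc = "".join(comp[c] for c in reversed(window))
        s_rev = sum(log_odds[idx[c], j] for j, c in enumerate(rc))
        if s_rev >= cutoff:
            hits.add((start, "-", round(s_rev, 6)))
    return hits


def rwr_linear_solve(W: np.ndarray, p0: np.ndarray, restart: float) -> np.ndarray:
    """Closed-form random-walk-with-restart: (I - (1-r) W)^-1 r p0."""
    p0 = p0 / p0.sum()
    n = W.shape[0]
    return np.linalg.solve(np.eye(n) - (1 - restart) * W, restart * p0)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x)
        for x in range(k, min(n, K) + 1)
    ) / total


def hypergeom_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every possible draw of n from N items."""
    items = list(range(N))
    pathway = set(range(K))
    hits = sum(1 for draw in combinations(items, n) if len(pathway & set(draw)) >= k)
    return hits / math.comb(N, n)


def best_coverage(target_sets: list[set], degs: set, max_size: int) -> int:
    """Exhaustive max-coverage over every subset of at most max_size sets."""
    best = 0
    idx = range(len(target_sets))
    for size in range(1, max_size + 1):
        for combo in combinations(idx, size):
            covered = set().union(*(target_sets[i] & degs for i in combo))
            best = max(best, len(covered))
    return best
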