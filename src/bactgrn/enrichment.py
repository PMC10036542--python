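"""Hypergeometric pathway over-representation analysis.

Query gene sets (DEGs, module genes, operon-cluster genes) are tested
against each pathway with the upper-tail hypergeometric probability
P(X >= k); significance is raw p < 0.05, matching a pure-threshold
criterion, with Benjamini-Hochberg q-values additionally reported for
transparency (they do not drive the significance flag).  The background is
the pathway-annotated gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import false_discovery_control, hypergeom


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    query_size: int   # n: annotated query genes
    overlap: int      # k
    pathway_size: int  # K
    background: int   # N
    p_value: float
    q_value: float
    direction: str    # "up" | "down" | "none"
    significant: bool


class PathwayDB:
    """Pathway id -> gene set, over an annotated background universe."""

    def __init__(self, pathways: Mapping[str, Iterable[str]], background: set[str] | None = None):
        self.pathways = {name: set(genes) for name, genes in pathways.items()}
        if any(not g for g in self.pathways.values()):
            raise ValueError("empty pathway gene set")
        universe = set().union(*self.pathways.values()) if self.pathways else set()
        self.background = set(background) if background is not None else universe
        if not self.background:
            raise ValueError("empty background universe")
        for name, genes in self.pathways.items():
            if not genes <= self.background:
                raise ValueError(f"pathway {name!r} has genes outside the background")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts pathway genes (K of N in the background) among n drawn query
    genes.  k = 0 gives p = 1.
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    db: PathwayDB,
    direction: str = "none",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every pathway with overlap >= 1; results sorted by ascending p.

    Query genes outside the background are dropped (set semantics: order
    and duplicates are irrelevant).
    """
    qset = set(query) & db.background
    n, N = len(qset), len(db.background)
    raw = []
    for name in sorted(db.pathways):
        genes = db.pathways[name]
        k = len(qset & genes)
        if k < 1:
            continue
        raw.append((name, k, len(genes), hypergeom_p(k, len(genes), n, N)))
    if not raw:
        return []
    qvals = false_discovery_control([p for *_, p in raw], method="bh")
    results = [
        EnrichmentResult(name, n, k, K, N, p, float(q), direction, p < alpha)
        for (name, k, K, p), q in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.pathway, r.overlap, r.pathway_size, r.query_size, r.background,
             r.p_value, r.q_value, r.direction, r.significant)
            for r in results
        ],
        columns=["pathway", "k", "K", "n", "N", "p", "q", "direction", "significant"],
    )
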