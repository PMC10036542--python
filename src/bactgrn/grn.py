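"""Bipartite TF -> target network assembly.

Each surviving binding site is assigned to its closest gene (interval
distance, 0 when overlapping) within a configurable maximum distance; the
deduplicated (TF, target) pairs form the gene regulatory network.  Edges
are unsigned: the motif evidence carries no activation/repression polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import Gene, GenomeAnnotation
from .motif import BindingSite


@dataclass(frozen=True)
class Edge:
    tf: str
    target: str
    score: float  # best supporting site score
    distance: int  # bp from that site to the target gene (0 = overlap)


@dataclass
class GRN:
    """Directed bipartite regulatory network: TFs -> target genes."""

    edges: list[Edge]
    tfs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        pairs = {(e.tf, e.target) for e in self.edges}
        if len(pairs) != len(self.edges):
            raise ValueError("duplicate (tf, target) pairs in GRN")
        for e in self.edges:
            if e.tf not in self.tfs:
                raise ValueError(f"edge source {e.tf!r} not in TF set")
            if e.distance < 0:
                raise ValueError("negative site-gene distance")

    @property
    def targets(self) -> set[str]:
        return {e.target for e in self.edges}

    def targets_of(self, tf: str) -> set[str]:
        return {e.target for e in self.edges if e.tf == tf}

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.tf, e.target) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.tf, e.target, e.score, e.distance) for e in self.edges],
            columns=["tf", "target", "score", "distance"],
        ).sort_values(["tf", "target"], ignore_index=True)


def _interval_distance(site: BindingSite, gene: Gene) -> int:
    if site.end <= gene.start:
        return gene.start - site.end + 1
    if gene.end <= site.start:
        return site.start - gene.end + 1
    return 0  # overlap


def _is_downstream(site: BindingSite, gene: Gene) -> bool:
    """Gene start lies downstream of the site on the site's strand."""
    if site.strand == "+":
        return gene.start >= site.end
    return gene.end <= site.start


def assign_targets(
    sites: Iterable[BindingSite],
    annotation: GenomeAnnotation,
    max_distance: Optional[int] = 1000,
) -> list[Edge]:
    """Closest-gene target assignment for every binding site.

    Ties on distance are broken by (a) the gene downstream of the site on
    the site's strand, then (b) the smaller gene start.  Sites farther than
    `max_distance` from every gene produce no edge; `max_distance=None`
    disables the cap.
    """
    by_contig: dict[str, list[Gene]] = {}
    for g in annotation:
        by_contig.setdefault(g.contig, []).append(g)
    edges = []
    for site in sorted(sites):
        if site.contig not in by_contig:
            raise KeyError(f"site on unknown contig {site.contig!r}")
        best: tuple | None = None
        for gene in by_contig[site.contig]:
            d = _interval_distance(site, gene)
            if max_distance is not None and d > max_distance:
                continue
            key = (d, 0 if _is_downstream(site, gene) else 1, gene.start)
            if best is None or key < best[0]:
                best = (key, gene)
        if best is not None:
            d = best[0][0]
            edges.append(Edge(site.tf_id, best[1].gene_id, site.score, d))
    return edges


def build_grn(raw_edges: Sequence[Edge], tf_ids: Iterable[str]) -> GRN:
    """Collapse duplicate (tf, target) pairs keeping the best site score.

    `tf_ids` is the full screened TF set; TFs without any surviving site
    remain in the network's TF set with no out-edges.  TF self-edges
    (autoregulation) are retained.
    """
    tf_set = set(tf_ids)
    best: dict[tuple[str, str], Edge] = {}
    for e in raw_edges:
        if e.tf not in tf_set:
            raise ValueError(f"edge source {e.tf!r} absent from TF screen result")
        key = (e.tf, e.target)
        cur = best.get(key)
        if cur is None or (e.score, -e.distance) > (cur.score, -cur.distance):
            best[key] = e
    edges = sorted(best.values(), key=lambda e: (e.tf, e.target))
    return GRN(edges=edges, tfs=tf_set)


def read_edges_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def grn_from_frame(df: pd.DataFrame, tf_ids: Iterable[str]) -> GRN:
    edges = [
        Edge(r.tf, r.target, float(r.score), int(r.distance))
        for r in df.itertuples(index=False)
    ]
    return build_grn(edges, tf_ids)
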