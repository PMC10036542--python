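"""File-format boundary for the pipeline.

Everything internal uses 0-based half-open coordinates; GFF3's 1-based
inclusive convention is converted here and nowhere else.  All artifacts are
plain text (FASTA, GFF3, TSV, BED, bedGraph, GMT, JSON, JASPAR-style PWM
blocks) so every stage output can be inspected with standard tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"


@dataclass(frozen=True, order=True)
class Gene:
    """A gene record: 0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int
    gene_id: str
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


class GenomeAnnotation:
    """Ordered gene records over a contig set.

    Genes are kept sorted by (contig, start); lookup by id is O(1).
    """

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = sorted(genes, key=lambda g: (g.contig, g.start))
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids in annotation")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def on_contig(self, contig: str) -> list[Gene]:
        return [g for g in self.genes if g.contig == contig]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 (gene features only)

def write_gff3(path: str | Path, annotation: GenomeAnnotation, source: str = "bactgrn") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            # 0-based half-open -> 1-based inclusive
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3(path: str | Path) -> GenomeAnnotation:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            genes.append(
                Gene(
                    contig=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    gene_id=attrs.get("ID", f"{fields[0]}:{fields[3]}"),
                    strand=fields[6],
                )
            )
    return GenomeAnnotation(genes)


# ---------------------------------------------------------------------------
# bedGraph (0-based half-open)

def write_bedgraph(path: str | Path, contig: str, values: np.ndarray) -> None:
    """Run-length encode a per-base coverage vector; zero runs are omitted."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        if values.size == 0:
            return
        breaks = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [values.size]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path, contig: str, length: int) -> np.ndarray:
    """Expand a bedGraph into a per-base vector; uncovered bases are 0."""
    values = np.zeros(length, dtype=float)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            c, s, e, v = line.split()[:4]
            if c != contig:
                continue
            values[int(s):int(e)] = float(v)
    return values


# ---------------------------------------------------------------------------
# GMT gene sets

def write_gmt(path: str | Path, pathways: Mapping[str, Sequence[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            pathways[fields[0]] = set(fields[2:])
    return pathways


# ---------------------------------------------------------------------------
# JASPAR-style PWM blocks: >id then four rows A/C/G/T of L numbers each

def write_pwms(path: str | Path, pwms: Mapping[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for name, mat in pwms.items():
            mat = np.asarray(mat, dtype=float)
            fh.write(f">{name}\n")
            for base, row in zip(NUCLEOTIDES, mat):
                fh.write(f"{base}  [ " + "  ".join(f"{x:.6f}" for x in row) + " ]\n")


def read_pwms(path: str | Path) -> dict[str, np.ndarray]:
    pwms: dict[str, np.ndarray] = {}
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms[name] = np.array(rows, dtype=float)
                name, rows = line[1:].split()[0], []
            else:
                nums = line.replace("[", " ").replace("]", " ").split()[1:]
                rows.append([float(x) for x in nums])
    if name is not None:
        pwms[name] = np.array(rows, dtype=float)
    return pwms


# ---------------------------------------------------------------------------
# small helpers

def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
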