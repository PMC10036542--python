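"""Staged pipeline runner.

Each stage reads the plain-text artifacts of its upstream stages from the
output directory, runs one analysis step, and writes its own artifacts plus
a manifest entry (config hash, seed, record counts).  Stage order:

    simulate -> degs -> grn -> modules -> operons -> enrich

`run("all", ...)` executes everything in order.  Stage seeds are fanned out
deterministically from the one global seed via a stable per-stage hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .enrichment import PathwayDB, enrich, results_frame
from .expression import ExpressionMatrix, cluster_expression, deg_table
from .grn import assign_targets, build_grn, grn_from_frame
from .homology import KarlinParams, screen_tfs
from .motif import read_sites_bed, scan_all, transfer_pwm, write_sites_bed
from .netmodules import PropagationConfig, extract_modules, membership_table
from .operons import (
    OperonDetectorConfig, chain_operons, cluster_operons, detect_operon_pairs,
    operon_values,
)
from .synth import CONTIG, GeneratorConfig, generate_dataset, write_dataset

logger = logging.getLogger("bactgrn")

STAGES = ("simulate", "degs", "grn", "modules", "operons", "enrich")

# artifacts each stage requires before it can run
_REQUIRES = {
    "simulate": (),
    "degs": ("counts.tsv",),
    "grn": ("genome.fasta", "annotation.gff3", "proteome.faa", "tfdb.faa", "tfdb_pwms.txt"),
    "modules": ("edges.tsv", "degs.tsv", "tf_screen.tsv"),
    "operons": ("annotation.gff3", "counts.tsv", "coverage"),
    "enrich": ("pathways.gmt", "degs.tsv", "modules.json"),
}


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with per-module defaults."""

    outdir: str = "bactgrn_out"
    seed: int = 0
    # synthetic generator (used by the `simulate` stage)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # expression
    deg_threshold: float = 1.0
    pseudocount: float = 1.0
    linkage_cut: float = 3.0
    # homology screen
    e_threshold: float = 0.05
    # motif scan
    scan_threshold_frac: float = 0.8
    motif_pseudocount: float = 0.01
    # target assignment
    max_distance: Optional[int] = 1000
    # propagation
    restart: float = 0.5
    prop_tol: float = 1e-6
    prop_max_iter: int = 1000
    # operons
    operon_vote_threshold: int = 3
    operon_k: int = 6
    # enrichment
    enrich_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("generator", {}).items()
        })
        known = {f for f in cls.__dataclass_fields__} - {"generator"}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(generator=gen, **raw)

    def config_hash(self) -> str:
        # outdir is a location, not an analysis parameter
        params = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return (self.seed + zlib.crc32(stage.encode())) % (2**31)


class StageError(RuntimeError):
    pass


def _check_requirements(stage: str, out: Path) -> None:
    missing = [a for a in _REQUIRES[stage] if not (out / a).exists()]
    if missing:
        raise StageError(
            f"stage {stage!r} needs artifacts from earlier stages; "
            f"missing: {missing} — run the upstream stage(s) first"
        )


def _update_manifest(out: Path, stage: str, cfg: PipelineConfig, counts: dict) -> None:
    path = out / "manifest.json"
    manifest = bio.read_json(path) if path.exists() else {}
    manifest[stage] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "records": counts,
    }
    bio.write_json(path, manifest)


def _load_expression(out: Path, cfg: PipelineConfig) -> ExpressionMatrix:
    counts = bio.read_counts_tsv(out / "counts.tsv")
    tps = cfg.generator.timepoints
    return ExpressionMatrix(counts, tps, cfg.generator.control)


def run_simulate(cfg: PipelineConfig) -> dict:
    gen_cfg = cfg.generator
    if gen_cfg.seed != cfg.stage_seed("simulate"):
        gen_cfg = GeneratorConfig(**{**asdict(gen_cfg), "seed": cfg.stage_seed("simulate")})
    ds = generate_dataset(gen_cfg)
    write_dataset(ds, cfg.outdir)
    return {
        "genes": len(ds.annotation),
        "ref_tfs": len(ds.ref_pwms),
        "planted_tfs": len(ds.truth.true_tfs),
        "planted_edges": len(ds.truth.true_edges),
        "planted_operons": len(ds.truth.true_operons),
        "samples": ds.counts.shape[1],
    }


def run_degs(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    matrix = _load_expression(out, cfg)
    degs = deg_table(matrix, cfg.deg_threshold, cfg.pseudocount)
    bio.write_tsv(out / "degs.tsv", degs)
    # fold-change profiles of the DEG union, clustered as in the heatmap view
    lfc = pd.DataFrame({
        tp: np.log2(
            (matrix.counts[matrix.replicates(tp)].mean(axis=1) + cfg.pseudocount)
            / (matrix.counts[matrix.replicates(matrix.control)].mean(axis=1) + cfg.pseudocount)
        )
        for tp in matrix.timepoints if tp != matrix.control
    })
    deg_union = sorted(set(degs["gene"]))
    n_clusters = 0
    if len(deg_union) >= 2:
        labels = cluster_expression(lfc.loc[deg_union], cfg.linkage_cut)
        labels.rename_axis("gene").to_frame().to_csv(out / "deg_clusters.tsv", sep="\t")
        n_clusters = int(labels.nunique())
    matrix.zscores().rename_axis("gene").to_csv(out / "zscores.tsv", sep="\t")
    return {
        "deg_records": len(degs),
        "unique_degs": len(deg_union),
        "expression_clusters": n_clusters,
    }


def run_grn(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    genome = bio.read_fasta(out / "genome.fasta")
    annotation = bio.read_gff3(out / "annotation.gff3")
    proteome = bio.read_fasta(out / "proteome.faa")
    ref_proteins = bio.read_fasta(out / "tfdb.faa")
    ref_pwms = bio.read_pwms(out / "tfdb_pwms.txt")

    screen = screen_tfs(proteome, ref_proteins, cfg.e_threshold, params=KarlinParams())
    screen_df = pd.DataFrame(
        [(h.query, h.subject, h.score, h.evalue, h.identity) for h in screen.values()],
        columns=["query", "donor", "score", "evalue", "identity"],
    ).sort_values("query", ignore_index=True)
    bio.write_tsv(out / "tf_screen.tsv", screen_df)

    pwms = transfer_pwm(screen, ref_pwms)
    sites = scan_all(pwms, genome, cfg.scan_threshold_frac,
                     pseudocount=cfg.motif_pseudocount)
    write_sites_bed(out / "sites.bed", sites)

    raw_edges = assign_targets(sites, annotation, cfg.max_distance)
    network = build_grn(raw_edges, screen.keys())
    bio.write_tsv(out / "edges.tsv", network.to_frame())
    return {
        "tfs_screened": len(screen),
        "binding_sites": len(sites),
        "edges": len(network.edges),
    }


def run_modules(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    edges = pd.read_csv(out / "edges.tsv", sep="\t")
    screen = pd.read_csv(out / "tf_screen.tsv", sep="\t")
    degs = pd.read_csv(out / "degs.tsv", sep="\t")
    network = grn_from_frame(edges, screen["query"])
    prop = PropagationConfig(cfg.restart, cfg.prop_tol, cfg.prop_max_iter)
    tps = [t for t in cfg.generator.timepoints if t != cfg.generator.control]
    modules = extract_modules(network, degs, tps, prop)
    payload = {
        tp: {
            "major_tfs": [[tf, score] for tf, score in m.major_tfs],
            "targets": sorted(m.targets),
            "edges": sorted(list(e) for e in m.edges),
            "uncovered": sorted(m.uncovered),
            "influence": {k: round(v, 6) for k, v in m.influence.items()},
        }
        for tp, m in modules.items()
    }
    bio.write_json(out / "modules.json", payload)
    membership_table(modules).to_csv(out / "tf_membership.tsv", sep="\t")
    return {
        "timepoints": len(modules),
        "major_tfs_earliest": len(modules[tps[0]].major_tfs),
        "targets_earliest": len(modules[tps[0]].targets),
    }


def run_operons(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    annotation = bio.read_gff3(out / "annotation.gff3")
    matrix = _load_expression(out, cfg)
    genome_len = max(g.end for g in annotation) + 500
    coverage = {}
    for p in sorted((out / "coverage").glob("*.bedGraph")):
        coverage[p.stem] = bio.read_bedgraph(p, CONTIG, genome_len)
    pair_calls = detect_operon_pairs(
        coverage, annotation, matrix.timepoint_means(), OperonDetectorConfig(
            vote_threshold=cfg.operon_vote_threshold)
    )
    pd.DataFrame(
        [(c.gene1, c.gene2, *c.votes, c.n_votes) for c in pair_calls],
        columns=["gene1", "gene2", "v_gap", "v_kw", "v_gapcov", "v_corr",
                 "v_window", "v_fold", "votes"],
    ).to_csv(out / "operon_pairs.tsv", sep="\t", index=False)
    operons = chain_operons(pair_calls, annotation, cfg.operon_vote_threshold)
    pd.DataFrame(
        [(f"operon_{i+1}", ",".join(op.members), ",".join(map(str, op.pair_votes)))
         for i, op in enumerate(operons)],
        columns=["operon", "members", "pair_votes"],
    ).to_csv(out / "operons.tsv", sep="\t", index=False)
    profiles = operon_values(operons, matrix.zscores())
    profiles.to_csv(out / "operon_profiles.tsv", sep="\t")
    n_clustered = 0
    if len(profiles) >= cfg.operon_k:
        labels, centroids = cluster_operons(
            profiles, cfg.operon_k, cfg.stage_seed("operons")
        )
        labels.to_frame().to_csv(out / "operon_clusters.tsv", sep="\t")
        centroids.to_csv(out / "operon_cluster_means.tsv", sep="\t")
        n_clustered = int(labels.nunique())
    in_operons = {g for op in operons for g in op.members}
    return {
        "candidate_pairs": len(pair_calls),
        "operons": len(operons),
        "genes_in_operons": len(in_operons),
        "operon_clusters": n_clustered,
    }


def run_enrich(cfg: PipelineConfig) -> dict:
    out = Path(cfg.outdir)
    db = PathwayDB(bio.read_gmt(out / "pathways.gmt"))
    degs = pd.read_csv(out / "degs.tsv", sep="\t")
    modules = bio.read_json(out / "modules.json")
    frames = []
    for tp, sub in degs.groupby("timepoint"):
        for direction, genes in sub.groupby("direction")["gene"]:
            res = enrich(genes, db, direction, cfg.enrich_alpha)
            f = results_frame(res)
            f.insert(0, "query", f"degs_{tp}_{direction}")
            frames.append(f)
    for tp, m in modules.items():
        res = enrich(m["targets"], db, "none", cfg.enrich_alpha)
        f = results_frame(res)
        f.insert(0, "query", f"module_{tp}")
        frames.append(f)
    frames = [f for f in frames if len(f)]
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["query", "pathway", "k", "K", "n", "N", "p", "q", "direction",
                 "significant"]
    )
    bio.write_tsv(out / "enrichment.tsv", table)
    return {
        "tests": len(table),
        "significant": int(table["significant"].sum()) if len(table) else 0,
    }


_RUNNERS = {
    "simulate": run_simulate,
    "degs": run_degs,
    "grn": run_grn,
    "modules": run_modules,
    "operons": run_operons,
    "enrich": run_enrich,
}


def run(stage: str, cfg: PipelineConfig) -> dict:
    """Run one stage (or "all"); returns the manifest record counts."""
    if stage == "all":
        results = {}
        for s in STAGES:
            results[s] = run(s, cfg)
        return results
    if stage not in _RUNNERS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _check_requirements(stage, out)
    logger.info("running stage %s (outdir=%s, seed=%d)", stage, cfg.outdir, cfg.seed)
    counts = _RUNNERS[stage](cfg)
    _update_manifest(out, stage, cfg, counts)
    logger.info("stage %s done: %s", stage, counts)
    return counts
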