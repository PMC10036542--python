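"""Synthetic bacterium and irradiation time-course with planted ground truth.

The generator emits a complete toy dataset mirroring the structure of a
UVC-irradiation experiment on an unannotated bacterium: a single-contig
genome with annotated genes, a reference database of prokaryotic TFs
(protein + PWM), a strain proteome in which some proteins are diverged
copies of reference TFs, planted TF binding sites upstream of regulon
genes, same-strand co-transcribed operon blocks with continuous coverage,
a negative-binomial count matrix over a control and four post-treatment
timepoints (3 replicates each), and pathway gene sets.  The regulatory
signal is a two-layer cascade: a master TF shifts its direct targets and
one intermediate TF, which shifts the rest of the regulon with attenuated
amplitude; the effect decays over the time course.

Two consistency guarantees make the planted truth exact by construction:
chance motif matches above the scan threshold are scrubbed from the genome
before sites are planted, and random (non-TF) strain proteins are
rejection-sampled so none passes the homology screen's e-value rule.
Without them a "random" k-mer occurrence would be a real binding site under
the model while the truth labels said otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as bio
from .homology import KarlinParams, evalue, _make_aligner
from .io import Gene, GenomeAnnotation
from .motif import PWM, pwm_log_odds, reverse_complement, scan_genome

AMINO_ACIDS_STR = "ACDEFGHIKLMNPQRSTVWY"
CONTIG = "toy_contig"

# per-timepoint log2 archetype patterns for operon dynamics (control first);
# only the two "early" archetypes cross the |log2FC| >= 1 DEG threshold, so
# the planted DEG signal decays over the course as a whole
ARCHETYPES = {
    "early_up": [0.0, 1.5, 0.8, 0.3, 0.1],
    "early_down": [0.0, -1.5, -0.8, -0.3, -0.1],
    "late_up": [0.0, 0.1, 0.5, 0.8, 0.9],
    "late_down": [0.0, -0.1, -0.5, -0.8, -0.9],
    "transient": [0.0, 0.9, 0.3, -0.6, -0.9],
    "flat": [0.0, 0.0, 0.0, 0.0, 0.0],
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic experiment."""

    n_genes: int = 300
    n_ref_tfs: int = 20
    n_strain_tfs: int = 10
    motif_length_range: tuple[int, int] = (8, 14)
    n_operons: int = 40
    operon_size_range: tuple[int, int] = (2, 5)
    operon_gap_max: int = 50
    timepoints: tuple[str, ...] = ("control", "5min", "1h", "3h", "12h")
    replicates: int = 3
    nb_dispersion: float = 0.1
    master_effect_log2: float = 2.0
    effect_decay: tuple[float, ...] = (1.0, 0.5, 0.2, 0.1)
    seed: int = 0
    # cascade wiring
    n_direct_targets: int = 12      # includes the intermediate TF
    n_indirect_targets: int = 12
    indirect_attenuation: float = 0.75
    other_tf_regulon: int = 3
    # geometry
    gene_length_range: tuple[int, int] = (300, 1500)
    operon_gap_min: int = 5
    intergenic_range: tuple[int, int] = (150, 400)
    promoter_window: int = 300
    site_offset_range: tuple[int, int] = (10, 40)
    # expression / coverage
    base_mean_range: tuple[float, float] = (50.0, 500.0)
    coverage_per_count: float = 200.0  # per-base coverage = counts * this / length
    coverage_noise_sd: float = 0.2
    coverage_noise_bin: int = 25
    # proteins / motifs
    tf_mutation_rate: float = 0.08
    protein_length_range: tuple[int, int] = (100, 300)
    motif_dominance_range: tuple[float, float] = (0.85, 0.97)
    consensus_planting: bool = True
    scan_threshold_frac: float = 0.8
    screen_e_threshold: float = 0.05
    deg_truth_threshold: float = 1.0
    # pathways
    n_random_pathways: int = 19
    pathway_size_range: tuple[int, int] = (10, 30)

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_ref_tfs", "n_strain_tfs", "n_operons", "replicates"):
            if getattr(self, name) < 0 or (name in ("n_genes", "n_ref_tfs", "replicates") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.operon_size_range[0] < 2:
            raise ValueError("operon_size_range minimum must be >= 2")
        if len(self.effect_decay) != len(self.timepoints) - 1:
            raise ValueError("effect_decay length must equal post-control timepoints")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        max_site = self.site_offset_range[1] + self.motif_length_range[1]
        if max_site > self.promoter_window:
            raise ValueError("promoter window shorter than site offset + motif")

    @property
    def control(self) -> str:
        return self.timepoints[0]

    @property
    def post_timepoints(self) -> tuple[str, ...]:
        return self.timepoints[1:]

    def sample_ids(self) -> list[str]:
        return [f"{tp}_{r + 1}" for tp in self.timepoints for r in range(self.replicates)]


@dataclass
class SyntheticTruth:
    """Planted ground truth, populated incrementally by the generator."""

    true_tfs: set[str] = field(default_factory=set)
    tf_donors: dict[str, str] = field(default_factory=dict)
    master_tf: str = ""
    intermediate_tf: str = ""
    true_edges: set[tuple[str, str]] = field(default_factory=set)
    true_operons: list[tuple[str, ...]] = field(default_factory=list)
    operon_archetypes: list[str] = field(default_factory=list)
    true_degs: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    planted_sites: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    expected_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)

    def operon_pairs(self) -> set[tuple[str, str]]:
        return {
            (op[i], op[i + 1]) for op in self.true_operons for i in range(len(op) - 1)
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_tfs"] = sorted(self.true_tfs)
        d["true_edges"] = sorted(list(e) for e in self.true_edges)
        d["true_operons"] = [list(op) for op in self.true_operons]
        d["true_degs"] = {
            tp: {k: sorted(v) for k, v in sets.items()}
            for tp, sets in self.true_degs.items()
        }
        d["planted_sites"] = [list(s) for s in self.planted_sites]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        t = cls()
        t.true_tfs = set(d["true_tfs"])
        t.tf_donors = dict(d["tf_donors"])
        t.master_tf = d["master_tf"]
        t.intermediate_tf = d["intermediate_tf"]
        t.true_edges = {tuple(e) for e in d["true_edges"]}
        t.true_operons = [tuple(op) for op in d["true_operons"]]
        t.operon_archetypes = list(d["operon_archetypes"])
        t.true_degs = {
            tp: {k: set(v) for k, v in sets.items()}
            for tp, sets in d["true_degs"].items()
        }
        t.planted_sites = [tuple(s) for s in d["planted_sites"]]
        t.expected_log2fc = {g: dict(v) for g, v in d["expected_log2fc"].items()}
        return t


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    ref_proteins: dict[str, str]
    ref_pwms: dict[str, np.ndarray]
    proteome: dict[str, str]
    counts: pd.DataFrame
    coverage: dict[str, np.ndarray]
    pathways: dict[str, list[str]]
    truth: SyntheticTruth


def _rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _dna_str(arr: np.ndarray) -> str:
    return "".join("ACGT"[i] for i in arr)


# ---------------------------------------------------------------------------
# genome layout

def generate_genome(
    config: GeneratorConfig,
) -> tuple[dict[str, str], GenomeAnnotation, SyntheticTruth]:
    """Lay out transcription units on a single random contig.

    Operon blocks are adjacent same-strand genes with intra-operon gaps of
    at most `operon_gap_max` bp; all other intergenic gaps are at least
    `intergenic_range[0]` bp so unit boundaries are unambiguous.
    """
    rng = _rng(config, 1)
    size_lo, size_hi = config.operon_size_range
    if config.n_operons * size_hi > config.n_genes:
        raise ValueError(
            f"infeasible sizing: {config.n_operons} operons of up to {size_hi} "
            f"genes cannot fit in {config.n_genes} genes"
        )
    sizes = rng.integers(size_lo, size_hi + 1, size=config.n_operons)
    n_single = config.n_genes - int(sizes.sum())
    # units: ("operon", size) and ("single", 1), shuffled into genome order
    units = [("operon", int(s)) for s in sizes] + [("single", 1)] * n_single
    rng.shuffle(units)

    truth = SyntheticTruth()
    genes: list[Gene] = []
    pos = config.intergenic_range[1]  # leading margin
    gidx = 0
    for kind, size in units:
        strand = "+" if rng.random() < 0.5 else "-"
        members = []
        for j in range(size):
            length = int(rng.integers(*config.gene_length_range, endpoint=True))
            gid = f"g{gidx + 1:04d}"
            genes.append(Gene(CONTIG, pos, pos + length, gid, strand))
            members.append(gid)
            gidx += 1
            pos += length
            if j < size - 1:
                pos += int(rng.integers(config.operon_gap_min, config.operon_gap_max, endpoint=True))
        if kind == "operon":
            truth.true_operons.append(tuple(members))
        pos += int(rng.integers(*config.intergenic_range, endpoint=True))
    genome_len = pos + config.intergenic_range[1]
    seq = _dna_str(_random_dna(rng, genome_len))
    return {CONTIG: seq}, GenomeAnnotation(genes), truth


# ---------------------------------------------------------------------------
# reference TF database

def generate_tf_database(
    config: GeneratorConfig,
) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    """Reference TF records: a random protein and a sharp random PWM each."""
    rng = _rng(config, 2)
    proteins: dict[str, str] = {}
    pwms: dict[str, np.ndarray] = {}
    aa = np.array(list(AMINO_ACIDS_STR))
    for i in range(config.n_ref_tfs):
        name = f"refTF{i + 1:02d}"
        plen = int(rng.integers(*config.protein_length_range, endpoint=True))
        proteins[name] = "".join(rng.choice(aa, size=plen))
        L = int(rng.integers(*config.motif_length_range, endpoint=True))
        mat = np.empty((4, L))
        for j in range(L):
            dom = int(rng.integers(0, 4))
            p = float(rng.uniform(*config.motif_dominance_range))
            col = np.full(4, (1 - p) / 3)
            col[dom] = p
            mat[:, j] = col
        pwms[name] = mat
    return proteins, pwms


# ---------------------------------------------------------------------------
# strain proteome

def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    aa = list(seq)
    for i in range(len(aa)):
        if rng.random() < rate:
            choices = AMINO_ACIDS_STR.replace(aa[i], "")
            aa[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(aa)


def generate_strain_proteome(
    config: GeneratorConfig,
    ref_proteins: Mapping[str, str],
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
) -> dict[str, str]:
    """One protein per gene; planted TFs are diverged reference-TF copies.

    TF genes are drawn from standalone (non-operon) genes so their
    promoters and regulons stay cleanly separable from operon structure.
    Random proteins are re-drawn until their best reference hit fails the
    screen's e-value rule, keeping the truth TF set exact.
    """
    if not ref_proteins:
        raise ValueError("reference TF database is empty")
    if config.n_strain_tfs > config.n_ref_tfs:
        raise ValueError("n_strain_tfs cannot exceed n_ref_tfs")
    rng = _rng(config, 3)
    operon_genes = {g for op in truth.true_operons for g in op}
    singles = [g for g in annotation.gene_ids() if g not in operon_genes]
    if len(singles) < config.n_strain_tfs:
        raise ValueError("not enough standalone genes to host the planted TFs")
    tf_genes = list(rng.choice(singles, size=config.n_strain_tfs, replace=False))
    donors = list(rng.choice(sorted(ref_proteins), size=config.n_strain_tfs, replace=False))

    params = KarlinParams()
    aligner = _make_aligner(params)
    db_len = sum(len(s) for s in ref_proteins.values())
    refs = sorted(ref_proteins)
    aa = np.array(list(AMINO_ACIDS_STR))

    def passes_screen(seq: str) -> bool:
        best = max(int(round(aligner.score(seq, ref_proteins[r]))) for r in refs)
        return evalue(best, len(seq), db_len, params) < config.screen_e_threshold

    proteome: dict[str, str] = {}
    for gid in annotation.gene_ids():
        if gid in tf_genes:
            donor = donors[tf_genes.index(gid)]
            proteome[gid] = _mutate_protein(ref_proteins[donor], config.tf_mutation_rate, rng)
            truth.true_tfs.add(gid)
            truth.tf_donors[gid] = donor
        else:
            for _ in range(100):
                plen = int(rng.integers(*config.protein_length_range, endpoint=True))
                seq = "".join(rng.choice(aa, size=plen))
                if not passes_screen(seq):
                    break
            else:
                raise RuntimeError("could not draw a non-TF protein failing the screen")
            proteome[gid] = seq
    if config.n_strain_tfs:
        truth.master_tf = tf_genes[0]
        truth.intermediate_tf = tf_genes[1] if config.n_strain_tfs > 1 else ""
    return proteome


# ---------------------------------------------------------------------------
# wiring, site planting, expression, coverage

def _wire_regulons(
    config: GeneratorConfig,
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> None:
    operon_genes = {g for op in truth.true_operons for g in op}
    pool = [
        g for g in annotation.gene_ids()
        if g not in operon_genes and g not in truth.true_tfs
    ]
    other_tfs = sorted(truth.true_tfs - {truth.master_tf, truth.intermediate_tf})
    need = (config.n_direct_targets - 1) + config.n_indirect_targets \
        + len(other_tfs) * config.other_tf_regulon
    if len(pool) < need:
        raise ValueError("not enough standalone genes for the configured regulons")
    chosen = list(rng.choice(pool, size=need, replace=False))
    direct = chosen[: config.n_direct_targets - 1]
    indirect = chosen[config.n_direct_targets - 1:
                      config.n_direct_targets - 1 + config.n_indirect_targets]
    rest = chosen[config.n_direct_targets - 1 + config.n_indirect_targets:]
    truth.true_edges |= {(truth.master_tf, t) for t in direct}
    if truth.intermediate_tf:
        truth.true_edges.add((truth.master_tf, truth.intermediate_tf))
        truth.true_edges |= {(truth.intermediate_tf, t) for t in indirect}
    for i, tf in enumerate(other_tfs):
        for t in rest[i * config.other_tf_regulon:(i + 1) * config.other_tf_regulon]:
            truth.true_edges.add((tf, t))


def _plant_site(
    genome_arr: np.ndarray,
    gene: Gene,
    pwm: PWM,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[int, int, str]:
    """Embed one motif occurrence in the gene's promoter; returns interval."""
    L = pwm.length
    offset = int(rng.integers(*config.site_offset_range, endpoint=True))
    if offset + L > config.promoter_window:
        raise ValueError("promoter window shorter than offset + motif")
    if config.consensus_planting:
        site_seq = pwm.consensus()
    else:
        site_seq = "".join(
            "ACGT"[rng.choice(4, p=pwm.matrix[:, j])] for j in range(L)
        )
    if gene.strand == "+":
        start = gene.start - offset - L
        planted = site_seq
    else:
        start = gene.end + offset
        planted = reverse_complement(site_seq)
    if start < 0 or start + L > genome_arr.size:
        raise ValueError("promoter window falls outside the contig")
    genome_arr[start:start + L] = np.frombuffer(planted.encode(), dtype=np.uint8)
    return start, start + L, gene.strand


def _scrub_genome(
    genome_arr: np.ndarray,
    ref_pwms: Mapping[str, np.ndarray],
    protected: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    max_rounds: int = 30,
) -> None:
    """Destroy chance motif matches above the scan threshold.

    Windows scoring >= threshold for any reference PWM, on either strand,
    are re-randomized unless they overlap a protected (planted) interval;
    repeated until the genome is clean.
    """
    for _ in range(max_rounds):
        seq = {CONTIG: genome_arr.tobytes().decode()}
        dirty = []
        for name in sorted(ref_pwms):
            lo = pwm_log_odds(PWM(name, ref_pwms[name]))
            for s in scan_genome(lo, seq, name, config.scan_threshold_frac):
                if not protected[s.start:s.end].any():
                    dirty.append((s.start, s.end))
        if not dirty:
            return
        for start, end in dirty:
            genome_arr[start:end] = np.frombuffer(
                _dna_str(_random_dna(rng, end - start)).encode(), dtype=np.uint8
            )
    raise RuntimeError("genome scrubbing did not converge")


def _expected_effects(config: GeneratorConfig, truth: SyntheticTruth,
                      gene_ids: Sequence[str]) -> pd.DataFrame:
    """Planted per-gene log2 shifts vs control, per timepoint."""
    eff = pd.DataFrame(
        0.0, index=list(gene_ids), columns=list(config.timepoints)
    )
    direct = {t for (s, t) in truth.true_edges if s == truth.master_tf}
    indirect = {t for (s, t) in truth.true_edges if s == truth.intermediate_tf}
    for i, tp in enumerate(config.post_timepoints):
        amp = config.master_effect_log2 * config.effect_decay[i]
        for g in direct:
            eff.loc[g, tp] = amp
        for g in indirect:
            eff.loc[g, tp] = amp * config.indirect_attenuation
    for k, op in enumerate(truth.true_operons):
        pattern = ARCHETYPES[truth.operon_archetypes[k]]
        eff.loc[list(op)] = np.array(pattern)[None, :]
    return eff


def _sample_counts(
    config: GeneratorConfig,
    effects: pd.DataFrame,
    base_means: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    cols = config.sample_ids()
    counts = np.empty((len(effects), len(cols)), dtype=np.int64)
    for ci, col in enumerate(cols):
        tp = col.rsplit("_", 1)[0]
        mean = base_means.to_numpy() * np.power(2.0, effects[tp].to_numpy())
        if config.nb_dispersion > 0:
            n = 1.0 / config.nb_dispersion
            p = n / (n + mean)
            counts[:, ci] = rng.negative_binomial(n, p)
        else:
            counts[:, ci] = rng.poisson(mean)
    return pd.DataFrame(counts, index=effects.index, columns=cols)


def _coverage_tracks(
    config: GeneratorConfig,
    annotation: GenomeAnnotation,
    counts: pd.DataFrame,
    truth: SyntheticTruth,
    genome_len: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-sample per-base coverage: gene bodies at a depth proportional to
    expression, operon gaps bridged at the flanking genes' level, other
    intergenic regions uncovered; multiplicative noise at bin resolution."""
    gap_pairs = {}
    for op in truth.true_operons:
        for a, b in zip(op, op[1:]):
            gap_pairs[(a, b)] = None
    genes = list(annotation)
    tracks: dict[str, np.ndarray] = {}
    n_bins = genome_len // config.coverage_noise_bin + 1
    for sample in counts.columns:
        base = np.zeros(genome_len)
        depth = {}
        for g in genes:
            depth[g.gene_id] = counts.at[g.gene_id, sample] * config.coverage_per_count / g.length
            base[g.start:g.end] = depth[g.gene_id]
        for g1, g2 in zip(genes, genes[1:]):
            if (g1.gene_id, g2.gene_id) in gap_pairs:
                level = 0.5 * (depth[g1.gene_id] + depth[g2.gene_id])
                base[g1.end:g2.start] = level
        noise = np.exp(rng.normal(0.0, config.coverage_noise_sd, size=n_bins))
        noise_track = np.repeat(noise, config.coverage_noise_bin)[:genome_len]
        tracks[sample] = np.round(base * noise_track, 3)
    return tracks


def plant_sites_and_expression(
    config: GeneratorConfig,
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    ref_pwms: Mapping[str, np.ndarray],
    truth: SyntheticTruth,
) -> tuple[dict[str, str], pd.DataFrame, dict[str, np.ndarray], SyntheticTruth]:
    """Wire the cascade, embed binding sites, and simulate counts/coverage."""
    rng = _rng(config, 4)
    if truth.true_tfs:
        _wire_regulons(config, annotation, truth, rng)
    arch_names = list(ARCHETYPES)
    truth.operon_archetypes = [
        arch_names[i % len(arch_names)] for i in range(len(truth.true_operons))
    ]
    rng.shuffle(truth.operon_archetypes)

    genome_arr = np.frombuffer(genome[CONTIG].encode(), dtype=np.uint8).copy()
    protected = np.zeros(genome_arr.size, dtype=bool)
    for tf, target in sorted(truth.true_edges):
        donor = truth.tf_donors[tf]
        pwm = PWM(donor, np.asarray(ref_pwms[donor]))
        start, end, strand = _plant_site(genome_arr, annotation[target], pwm, config, rng)
        protected[start:end] = True
        truth.planted_sites.append((tf, CONTIG, start, end, strand))
    _scrub_genome(genome_arr, ref_pwms, protected, config, rng)
    edited = {CONTIG: genome_arr.tobytes().decode()}

    gene_ids = annotation.gene_ids()
    effects = _expected_effects(config, truth, gene_ids)
    truth.expected_log2fc = {
        g: {tp: float(effects.at[g, tp]) for tp in config.post_timepoints}
        for g in gene_ids if effects.loc[g].abs().max() > 0
    }
    thr = config.deg_truth_threshold
    for tp in config.post_timepoints:
        truth.true_degs[tp] = {
            "up": set(effects.index[effects[tp] >= thr]),
            "down": set(effects.index[effects[tp] <= -thr]),
        }

    base_means = pd.Series(
        rng.uniform(*config.base_mean_range, size=len(gene_ids)), index=gene_ids
    )
    # operon members share a promoter: equalize their baseline transcription
    for op in truth.true_operons:
        shared = float(base_means.loc[list(op)].mean())
        base_means.loc[list(op)] = shared
    counts = _sample_counts(config, effects, base_means, rng)
    coverage = _coverage_tracks(config, annotation, counts, truth, genome_arr.size, rng)
    return edited, counts, coverage, truth


def generate_pathways(
    config: GeneratorConfig,
    truth: SyntheticTruth,
    gene_ids: Sequence[str],
) -> dict[str, list[str]]:
    """Toy pathway database: the master regulon as one planted pathway plus
    random gene sets; the background is the union of all pathway genes."""
    rng = _rng(config, 5)
    pathways: dict[str, list[str]] = {}
    regulon = sorted({t for (s, t) in truth.true_edges
                      if s in (truth.master_tf, truth.intermediate_tf)})
    if regulon:
        pathways["regulon_response"] = regulon
    for i in range(config.n_random_pathways):
        size = int(rng.integers(*config.pathway_size_range, endpoint=True))
        pathways[f"pathway_{i + 1:02d}"] = sorted(
            rng.choice(list(gene_ids), size=size, replace=False)
        )
    return pathways


# ---------------------------------------------------------------------------
# top level

def generate_dataset(config: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Run the full generator; deterministic for a fixed config seed."""
    genome, annotation, truth = generate_genome(config)
    ref_proteins, ref_pwms = generate_tf_database(config)
    proteome = generate_strain_proteome(config, ref_proteins, annotation, truth)
    genome, counts, coverage, truth = plant_sites_and_expression(
        config, genome, annotation, ref_pwms, truth
    )
    pathways = generate_pathways(config, truth, annotation.gene_ids())
    return SyntheticDataset(
        config, genome, annotation, ref_proteins, ref_pwms,
        proteome, counts, coverage, pathways, truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write every artifact as plain text; returns a name -> path manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "coverage").mkdir(exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "annotation": out / "annotation.gff3",
        "proteome": out / "proteome.faa",
        "tfdb_proteins": out / "tfdb.faa",
        "tfdb_pwms": out / "tfdb_pwms.txt",
        "counts": out / "counts.tsv",
        "pathways": out / "pathways.gmt",
        "truth": out / "truth.json",
    }
    bio.write_fasta(paths["genome"], ds.genome)
    bio.write_gff3(paths["annotation"], ds.annotation)
    bio.write_fasta(paths["proteome"], ds.proteome)
    bio.write_fasta(paths["tfdb_proteins"], ds.ref_proteins)
    bio.write_pwms(paths["tfdb_pwms"], ds.ref_pwms)
    ds.counts.rename_axis("gene").to_csv(paths["counts"], sep="\t")
    bio.write_gmt(paths["pathways"], ds.pathways)
    bio.write_json(paths["truth"], ds.truth.to_dict())
    for sample, track in ds.coverage.items():
        p = out / "coverage" / f"{sample}.bedGraph"
        bio.write_bedgraph(p, CONTIG, track)
    return {k: str(v) for k, v in paths.items()} | {
        "coverage_dir": str(out / "coverage")
    }
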