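# bactgrn

System-level analysis of bacterial stress-response transcriptomes for
strains with no curated regulatory annotation. Given a genome, a proteome,
a reference database of known prokaryotic transcription factors (TFs) with
their binding motifs, a time-series RNA-seq count matrix and per-base
coverage tracks, `bactgrn`:

1. **reconstructs a gene regulatory network (GRN) by homology** — strain
   proteins are screened against the reference TF set by exact local
   alignment (Smith–Waterman, BLOSUM62, Karlin–Altschul e-value < 0.05),
   each surviving TF inherits its closest reference's position weight
   matrix (PWM), the genome is scanned exhaustively on both strands for
   log-odds binding sites, and each site is assigned to its closest gene,
   yielding a bipartite TF → target network;
2. **extracts time-varying transcriptional modules** — per timepoint,
   differentially expressed genes (DEGs, |log2 FC| ≥ 1 vs control) seed a
   network propagation (random walk with restart), TFs are ranked by the
   correlation of their propagated influence with DEG magnitudes, and
   major TFs are selected greedily by marginal DEG coverage (influence
   maximization);
3. **detects operons from coverage** — adjacent same-strand gene pairs are
   voted on by six rule-based detectors (intergenic distance, Kruskal–
   Wallis coverage homogeneity, read-through depth, sliding-window
   continuity, co-expression, expression similarity); pairs with ≥ 3 of 6
   votes chain into operons, each summarized by its *operon value*
   O\_{i,t} = (1/n) Σ\_j g\_{i,t,j} — the mean z-scored expression of its
   n member genes at timepoint t — and operon-value profiles are k-means
   clustered into six dynamic patterns;
4. **runs hypergeometric pathway enrichment** (upper-tail P(X ≥ k),
   significant at p < 0.05) on DEG, module and operon-cluster gene sets.

Because real datasets of this kind need external databases and sequencing
archives, the package bundles a **synthetic-data generator** that emulates
the full experimental design with planted ground truth — a master-regulator
cascade driving an early, decaying response over a control and four
post-treatment timepoints (5 min, 1 h, 3 h, 12 h; 3 replicates), planted
promoter binding sites, and planted operon blocks with continuous
coverage — so every stage is testable end to end without downloads.

## Worked example

```bash
python examples/02_build_grn.py
```

```
TFs screened  : 10 of 300 proteins
binding sites : 48
edges         : 48
precision     : 1.000   recall: 1.000
```

All 10 planted TFs pass the e < 0.05 screen with their intended reference
donors, the motif scan recovers exactly the 48 planted promoter sites, and
closest-gene assignment reproduces the planted network perfectly.

```bash
python examples/03_time_varying_modules.py
```

```
timepoint  DEGs  major_TFs  covered_targets
     5min    75          2               23
       1h    20          2                6
       3h    22          1                1
      12h    22          2                2

top-influence TF at 5min: g0296 (planted master: g0296)
```

The module shrinks as the planted effect decays, and the highest-influence
TF at the earliest timepoint is the planted master regulator — recovered
from expression dynamics plus network structure alone. The other examples
(`examples/01_simulate_dataset.py`, `examples/04_operons_and_enrichment.py`)
cover dataset generation and the operon/enrichment stages.

## Command-line pipeline

The same analysis runs as a staged shell pipeline with plain-text
artifacts and a run manifest:

```bash
bactgrn all --outdir run0 --seed 0            # simulate → … → enrich
bactgrn operons --config config.yaml          # single stage, YAML config
```

Stages: `simulate`, `degs`, `grn`, `modules`, `operons`, `enrich`, `all`.

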