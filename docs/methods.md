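# Methods

This note documents the models, parameter choices and numerical details
behind each stage, and what the synthetic benchmark does and does not show
about real data.

## Homology-based TF screening

Strain proteins are aligned to every reference TF with exact local
(Smith–Waterman) dynamic programming under BLOSUM62 and affine gaps; a gap
of length k costs `open + k·extend` with open = 11, extend = 1 (the BLAST
"existence/extension" convention). Scoring is delegated to Biopython's
`PairwiseAligner` (exact DP in C); the test suite checks it against an
independent pure-Python Gotoh implementation.

Significance uses the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the
standard gapped-BLOSUM62 constants λ = 0.267, K = 0.041, where `n` is the
total residue count of the reference database. These constants are fixed,
not database-calibrated, and raw Smith–Waterman maxima run somewhat above
edge-corrected BLAST statistics, so the resulting e-values are
conservative stand-ins rather than calibrated probabilities: empirically
~15–20 % of length-150 random proteins clear E < 0.05 against the default
toy database (the nominal rate for a calibrated e-value would be ~5 %).
The screen keeps a protein iff its best hit has E < 0.05 (ties on score
broken by e-value, then subject id); the best hit is its PWM donor. An
optional candidate list restricts the screen to externally predicted TFs;
without one, the whole proteome is screened — a conservative superset
filtered by the same rule.

## Motif transfer and genome scanning

Each screened TF receives an exact copy of its donor's position
probability matrix. Scoring uses background-corrected log-odds in bits,
`log2((p + c·q)/((1+c)·q))` with pseudocount c = 0.01 and uniform
background by default. The scan is exhaustive over all windows on both
strands (minus-strand windows scored on the reverse complement, reported
in plus coordinates); ambiguous bases contribute 0 per position. The
emission threshold is a fraction of the maximum attainable score (default
0.8): fraction-of-max self-calibrates across motif lengths, is monotone
(lowering it only adds sites), and is exposed in config, as is an optional
promoter-window restriction (off by default — the default scans the whole
genome).

## Target assignment and network assembly

Each binding site is assigned to the gene minimizing interval distance
(0 when overlapping; bookended intervals count 1 bp, matching `bedtools
closest -d`). Ties go to the gene whose start lies downstream of the site
on the site's strand, then to the smaller start coordinate. Sites farther
than 1000 bp from every gene are dropped; the cap is configurable and can
be disabled. Duplicate (TF, target) pairs collapse keeping the best site
score; self-edges (autoregulation) are retained; edges are unsigned.

## DEG calling and expression clustering

Fold change is computed on replicate-mean counts with a pseudocount of 1,
`log2((mean_t + 1)/(mean_c + 1))`, so every value is finite including
all-zero genes. A gene is a DEG when |log2 FC| ≥ 1, boundary inclusive; no
dispersion-based test is applied, matching a pure threshold rule. No
library-size normalization is applied by default (the synthetic libraries
are mean-equalized by construction); per-gene z-scores are taken across
the five timepoint means, with zero-variance genes assigned all-zero rows.
Expression-profile clustering is agglomerative with average linkage on
Euclidean distances over z-scored profiles, cut at cophenetic distance 3.

## Network propagation and module selection

The propagation operator is the column-normalized TF → target adjacency;
nodes without out-edges keep zero columns, so their mass decays to the
restart distribution. Propagation iterates `p ← (1−r)·W·p + r·p₀` from the
normalized seed until the L1 change falls below 1e-6 (restart r = 0.5,
max 1000 iterations); the fixed point equals the direct linear solve
`(I−(1−r)W)⁻¹·r·p₀`, which the tests verify. A TF's influence at a
timepoint is the Pearson correlation between its propagated vector (unit
seed at the TF) and the DEG |log2 FC| magnitudes, both restricted to DEGs
present in the network; degenerate (constant) cases score 0. Magnitudes
rather than signed fold changes are used because the network's edges carry
no activation/repression polarity. Selection is greedy: walking down the
influence ranking, a TF joins the module iff it covers at least one
not-yet-covered DEG target, stopping when all coverable DEGs are covered.
This greedy-by-rank pass is sound (never exceeds the exhaustive
max-coverage optimum at the same budget) and matches it on ≥ 90 % of
small random instances. These parameter choices — restart 0.5, L1
tolerance, Pearson-on-DEGs influence, marginal-coverage selection — are
this package's own realization of the propagation + influence-maximization
design; all are config-exposed.

## Operon detection

Candidates are adjacent same-strand gene pairs (co-transcription requires
both). Six deterministic detectors vote, each covering a signal family a
trained operon classifier would exploit:

1. intergenic gap ≤ 100 bp;
2. Kruskal–Wallis H over per-base coverage of {gene1, gap, gene2} below
   the χ²(df = 2) critical value at α = 0.05 (homogeneous coverage);
3. mean gap coverage ≥ 0.5 × the smaller gene mean;
4. across-timepoint expression Pearson r ≥ 0.8;
5. minimum 25-bp sliding-window gap coverage ≥ 0.3 × the smaller gene
   mean;
6. gene-mean fold difference ≤ 4 with both means above a floor of 5.

A pair is operonic at ≥ 3 of 6 votes; positive pairs chain transitively
into maximal operons. Zero-length gaps vote from the two boundary bases.
Detectors 2/3/5/6 run on the mean coverage across all samples (making
votes invariant to sample order); detector 4 on timepoint-mean counts.
All thresholds sit in `OperonDetectorConfig`.

Operon values are exact means of member z-scores per timepoint. The
z-score axis is across the five timepoint means per gene (the alternative,
across samples, is available via the expression matrix but across-time is
the default because it makes operon profiles comparable in shape).
Profiles are clustered with k-means (k = 6, k-means++ init, 10 restarts,
fixed seed).

## Pathway enrichment

Upper-tail hypergeometric P(X ≥ k) per pathway (p = 1 at k = 0), query
genes outside the pathway-annotated background dropped with set
semantics, significance at raw p < 0.05 with no multiple-testing
correction driving the flag — Benjamini–Hochberg q-values are reported
alongside for transparency. The background is the annotated universe (the
union of pathway gene sets), not the whole genome.

## The synthetic benchmark

The generator emulates the structure of a UVC time-course on an
unannotated bacterium at desk scale: 300 non-overlapping genes
(300–1500 bp) on one ~335 kb linear contig; 40 operons of 2–5 same-strand
genes with ≤ 50 bp internal gaps; all other intergenic gaps ≥ 150 bp so
unit boundaries are unambiguous; a 20-TF reference database (proteins of
100–300 aa; PWMs of 8–14 bp with 0.85–0.97 column dominance); 10 strain
TFs as point-mutated reference copies (8 % substitution); a two-layer
cascade in which the master TF shifts 11 direct targets plus one
intermediate TF by +2 log2 units and the intermediate shifts 12 more with
0.75 attenuation (signal loss through the extra regulatory layer — it also
makes propagated influence genuinely rank the master first, since its
one-step mass lands on the higher-|log2FC| direct targets); per-timepoint
decay 1.0/0.5/0.2/0.1; eight background TFs with 3 planted targets each
and no expression effect; counts negative-binomial with dispersion 0.1
over base means of 50–500; operon dynamics drawn from six archetype
patterns (early-up/-down, late-up/-down, transient, flat) shared by
members; coverage proportional to expression with operon gaps bridged at
the flanking genes' level and multiplicative log-normal noise (σ = 0.2) at
25-bp bin resolution — bin-level noise keeps bedGraph tracks compact while
feeding the same detectors; pathway sets comprising the master regulon
plus 19 random pathways of 10–30 genes.

Two guarantees make the planted truth exact by construction. First, the
genome is scrubbed: windows scoring above the scan threshold for any
reference PWM, outside planted intervals, are re-randomized until none
remain — otherwise a chance consensus occurrence would be a genuine
binding site under the model while the truth labels said otherwise.
Second, random (non-TF) proteins are rejection-sampled until their best
reference hit fails the e < 0.05 screen, so the truth TF set is exactly
the screen's fixed point. Sites are planted as PWM consensus sequences
10–40 bp upstream of the target's strand-aware start (within the 300-bp
promoter window), which makes closest-gene assignment unambiguous and
site scores maximal.

What passing on this benchmark does **not** show: performance under
read-level noise (no FASTQ/alignment simulation), multi-contig or circular
genomes, diverged motifs (sites are planted at consensus), unequal library
sizes, TFs missing from the reference database, overlapping genes, or
operons with internal promoters. The benchmark validates the machinery and
its contracts, not field performance on real genomes.

## Problem sizes and determinism

Default analyses run on the 300-gene dataset (15 samples, ~335 kb genome)
in seconds to a couple of minutes on one CPU; the master-recovery summary
repeats the full analysis over ten generator seeds. Every stochastic step
threads an explicit seed: the generator derives independent per-operation
streams from its config seed, the pipeline fans its global seed out to
stages via a stable per-stage hash, and fixed seeds yield byte-identical
artifacts (the determinism tests compare emitted files byte for byte).
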