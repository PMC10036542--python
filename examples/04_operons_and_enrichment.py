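"""Detect operons from coverage, cluster their dynamics, run enrichment.

Adjacent same-strand gene pairs are voted on by six rule detectors over
coverage and co-expression signals (>= 3 of 6 votes = operon pair), chained
into operons, summarized by operon values (mean member z-score per
timepoint), and k-means-clustered into six dynamic patterns.  Gene sets are
then tested for pathway over-representation (hypergeometric, p < 0.05).
"""

from bactgrn import GeneratorConfig, generate_dataset
from bactgrn.enrichment import PathwayDB, enrich
from bactgrn.expression import ExpressionMatrix, deg_table
from bactgrn.operons import (
    chain_operons, cluster_operons, detect_operon_pairs, operon_values, pair_f1,
)

ds = generate_dataset(GeneratorConfig(seed=0))
matrix = ExpressionMatrix(ds.counts, ds.config.timepoints, "control")

calls = detect_operon_pairs(ds.coverage, ds.annotation, matrix.timepoint_means())
operons = chain_operons(calls, ds.annotation)
f1 = pair_f1(calls, ds.truth.operon_pairs())
in_ops = {g for op in operons for g in op.members}
print(f"candidate pairs : {len(calls)}")
print(f"operons called  : {len(operons)} (planted: {len(ds.truth.true_operons)})")
print(f"pairwise F1     : {f1:.3f}")
print(f"genes in operons: {len(in_ops)} / {len(ds.annotation)} "
      f"({100 * len(in_ops) / len(ds.annotation):.0f}%)")

profiles = operon_values(operons, matrix.zscores())
labels, centroids = cluster_operons(profiles, k=6, seed=0)
print("\noperons per dynamic cluster:", labels.value_counts().sort_index().tolist())

db = PathwayDB(ds.pathways)
degs = deg_table(matrix)
early_up = degs.query("timepoint == '5min' and direction == 'up'")["gene"]
top = enrich(early_up, db, "up")[0]
print(f"\ntop enriched pathway for 5min up-DEGs: {top.pathway} "
      f"(k={top.overlap}/{top.pathway_size}, p={top.p_value:.2e})")

# The planted regulon pathway should top the list: the master regulator's
# targets dominate the early up-regulated response.
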