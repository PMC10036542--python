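"""Generate a synthetic bacterium and irradiation time-course.

Builds the default toy dataset — a 300-gene single-contig genome with 40
planted operons, 10 strain TFs diverged from a 20-TF reference database, a
master-regulator cascade with binding sites planted in promoters, and
negative-binomial counts over control + 5min/1h/3h/12h (3 replicates) —
and writes every artifact as plain text.
"""

from bactgrn import GeneratorConfig, generate_dataset, write_dataset

config = GeneratorConfig(seed=0)
ds = generate_dataset(config)
paths = write_dataset(ds, "example_output/dataset")

print(f"genome length : {len(ds.genome['toy_contig']):,} bp")
print(f"genes         : {len(ds.annotation)}")
print(f"planted TFs   : {len(ds.truth.true_tfs)} (master: {ds.truth.master_tf})")
print(f"planted edges : {len(ds.truth.true_edges)}")
print(f"planted operons: {len(ds.truth.true_operons)}")
deg5 = ds.truth.true_degs["5min"]
print(f"planted DEGs at 5min: {len(deg5['up'])} up / {len(deg5['down'])} down")
print("artifacts:", ", ".join(sorted(paths)))

# The planted DEG counts shrink at later timepoints: the generator models an
# early transcriptional response that decays as the cell recovers.
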