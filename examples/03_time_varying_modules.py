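"""Extract per-timepoint transcriptional network modules.

DEGs (|log2FC| >= 1 vs control) are called per timepoint; the DEG signal is
propagated over the reconstructed network (random walk with restart 0.5);
TFs are ranked by the correlation of their propagated influence with DEG
magnitudes and selected greedily by marginal coverage.  The selected major
TFs + covered targets form each timepoint's module.
"""

from bactgrn import GeneratorConfig, generate_dataset, screen_tfs
from bactgrn.expression import ExpressionMatrix, deg_table
from bactgrn.grn import assign_targets, build_grn
from bactgrn.motif import scan_all, transfer_pwm
from bactgrn.netmodules import extract_modules

ds = generate_dataset(GeneratorConfig(seed=0))
screen = screen_tfs(ds.proteome, ds.ref_proteins)
sites = scan_all(transfer_pwm(screen, ds.ref_pwms), ds.genome)
net = build_grn(assign_targets(sites, ds.annotation), screen)

matrix = ExpressionMatrix(ds.counts, ds.config.timepoints, "control")
degs = deg_table(matrix, threshold=1.0)
modules = extract_modules(net, degs, list(ds.config.post_timepoints))

print("timepoint  DEGs  major_TFs  covered_targets")
for tp, mod in modules.items():
    n_degs = (degs["timepoint"] == tp).sum()
    print(f"{tp:>9}  {n_degs:>4}  {len(mod.major_tfs):>9}  {len(mod.targets):>15}")

early = modules[ds.config.post_timepoints[0]]
top_tf = max(early.influence, key=early.influence.get)
print(f"\ntop-influence TF at 5min: {top_tf} "
      f"(planted master: {ds.truth.master_tf})")

# The module shrinks over time as the planted effect decays, and the
# highest-influence TF at the earliest timepoint is the planted master
# regulator — the analysis recovers the cascade's apex from expression
# dynamics plus network structure alone.
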