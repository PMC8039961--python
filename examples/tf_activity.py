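"""TF-motif analysis: hypergeometric motif enrichment in driver promoter
DMRs against all called DMRs, TF-target correlation and activity scores
y = rho * log2(fold change).
"""

import numpy as np

from methdriver import drivers as drv
from methdriver.dmr import dmrs_to_frame, find_dmrs
from methdriver.simulate import SimulationConfig, simulate_dataset
from methdriver.tf import (activity_score, direction_comparison,
                           motif_cpg_report, motif_enrichment)

ds = simulate_dataset(SimulationConfig(seed=1))
called = find_dmrs(ds.matrix)
genes = ds.annotation.genes
coding = genes[genes["biotype"] == "coding"]
de = drv.differential_expression(ds.expression)
disc = drv.discovery_list(drv.select_best_per_gene(
    drv.pair_and_correlate(called, coding, ds.matrix, ds.expression)), de)

enr = motif_enrichment(set(disc["dmr_id"]), dmrs_to_frame(called),
                       ds.annotation.motifs)
print("motif enrichment in driver promoter DMRs (top 3 TF groups):")
print(enr.head(3).round(5).to_string(index=False))
print(f"planted TF group: {ds.truth.planted_tf} "
      f"(rank {int(enr.index[enr['tf'] == ds.truth.planted_tf][0]) + 1})")

# CpG content of the enriched TF's motif hits
hits = ds.annotation.motifs[ds.annotation.motifs["tf"] == enr.iloc[0]["tf"]]
report = motif_cpg_report(hits, ds.annotation.cpgs[["chrom", "pos"]])
print(f"\n{enr.iloc[0]['tf']}: {len(report)} motif hits, "
      f"{(report['cpg_inside'] > 0).mean():.0%} contain a CpG")

# activity scores for the discovery calls driven by the top TF
scores = [activity_score(r["rho"], r["fc"])
          for _, r in disc.iterrows()]
print(f"\nactivity scores over {len(scores)} driver targets: "
      f"mean {np.mean(scores):.2f} "
      f"({sum(s > 0 for s in scores)} concordant > 0)")

n_tfs = ds.annotation.motifs["tf"].nunique()
sig = enr[enr["q"] < 0.25]
cmp = direction_comparison(len(sig), 0, n_tfs)
print(f"direction comparison table {cmp['table']}: "
      f"Fisher p = {cmp['p']:.4f}")
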