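"""Score hypermethylated DMRs against 15-state chromatin segmentations.

Computes the fold enrichment F = O*G/(D*S) and the normalized score
E_i = F_i / sum(F) per state for one ESC epigenome, then classifies each
hyper DMR into poised-promoter / active-promoter / non-promoter subtypes
by its ESC-recurrent state.
"""

import pandas as pd

from methdriver.annotation import (classify_hyper_dmr, enrichment_table,
                                   promoter_table, subtype_summary)
from methdriver.core import GenomicInterval
from methdriver.dmr import dmrs_to_frame, find_dmrs
from methdriver.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=1))
called = find_dmrs(ds.matrix)
hyper = [d for d in called if d.direction == "hyper"]
hyper_frame = dmrs_to_frame(hyper)

G = sum(ds.annotation.chrom_sizes.values())
esc1 = ds.annotation.esc_ids[0]
enr = enrichment_table(hyper_frame, ds.annotation.states[esc1], G)
print(f"enrichment of {len(hyper)} hyper DMRs in {esc1} states "
      f"(top 5 by F):")
print(enr.sort_values("F", ascending=False).head(5).round(3)
      .to_string(index=False))
print(f"sum of normalized scores E: {enr['E'].sum():.6f}")

genes = ds.annotation.genes
promoters = promoter_table(genes[genes["biotype"] == "coding"])
esc_segs = {e: ds.annotation.states[e] for e in ds.annotation.esc_ids}
subtypes = pd.Series([classify_hyper_dmr(d.interval, promoters, esc_segs)
                      for d in hyper])
print("\nhyper-DMR subtypes (share of all hyper calls):")
print(subtype_summary(subtypes).round(1).to_string())
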