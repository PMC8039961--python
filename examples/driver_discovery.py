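"""Two-stage methylation-driver discovery and validation.

Discovery: pair called DMRs with promoter-overlapping genes, keep the most
negative methylation-expression Spearman correlation per gene, gate on
differential expression (paired t-test, |FC| > 2, FDR < 0.05) and on
rho < -0.3 (FDR < 0.05).  Validation: repeat the correlation screen on
probe betas in two independent cohorts; genes validated in both form the
high-confidence tier.
"""

from methdriver import drivers as drv
from methdriver.dmr import find_dmrs
from methdriver.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=1))
called = find_dmrs(ds.matrix)
genes = ds.annotation.genes
coding = genes[genes["biotype"] == "coding"]

de = drv.differential_expression(ds.expression)
pairs = drv.pair_and_correlate(called, coding, ds.matrix, ds.expression)
best = drv.select_best_per_gene(pairs)
disc = drv.discovery_list(best, de)
print(f"gene-DMR pairs: {len(pairs)}; discovery (primary) list: "
      f"{len(disc)} genes")

validations = {
    name: drv.validate_on_probes(disc["gene_id"], c.betas,
                                 c.probe_positions, c.expr, coding)
    for name, c in ds.cohorts.items()}
for name, v in validations.items():
    print(f"{name}: {int(v['validated'].sum())} of "
          f"{int(v['testable'].sum())} testable genes validated")

tiers = drv.tier_and_classify(disc, validations)
high = tiers[tiers["tier"] == "high"]
print(f"\nhigh-confidence drivers: {len(high)} "
      f"({(high['direction'] == 'hyper-driver').sum()} hyper, "
      f"{(high['direction'] == 'hypo-driver').sum()} hypo)")
truth = ds.truth.drivers
planted = set(truth.loc[truth["biotype"] == "coding", "gene_id"])
print(f"planted coding drivers recovered in discovery: "
      f"{len(set(disc['gene_id']) & planted)}/{len(planted)}")
print("\nstrongest five calls (most negative rho):")
cols = ["gene_id", "direction", "tier", "rho", "fc", "q_pair"]
print(tiers.sort_values("rho").head(5)[cols].round(3).to_string(index=False))
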