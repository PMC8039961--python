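"""Seeded end-to-end benchmark runs on planted-truth simulations.

These runners regenerate a dataset per replicate seed, execute the full
pipeline stage under test and measure recovery against the planted truth.
They back both the acceptance test suite and ``scripts/acceptance.py``.
Problem sizes follow the simulated study conditions: 18 tumor/normal pairs,
~50,000 CpG sites and 50 planted DMRs (delta 0.4, 15 CpGs) for the DMR
benchmark, and the full 20 hyper + 11 hypo coding-driver complement with
two validation cohorts for the driver benchmark.
"""

from __future__ import annotations

import numpy as np

from . import dmr as dmrmod
from . import drivers as drv
from . import tf as tfmod
from .annotation import enrichment_table
from .classify import evaluate_panel
from .dmr import dmrs_to_frame
from .simulate import (SimulationConfig, simulate_annotation,
                       simulate_dataset, simulate_marker_cohort,
                       simulate_methylome)

__all__ = ["rep_seed", "dmr_benchmark_config", "dmr_benchmark",
           "study_benchmark", "panel_benchmark", "jaccard"]


def rep_seed(seed: int, rep: int) -> int:
    """Deterministic replicate seed derived from the base seed."""
    return int((seed * 100_003 + rep * 7_919 + 1) % (2 ** 31 - 1))


def jaccard(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = max(0, min(a_end, b_end) - max(a_start, b_start) + 1)
    union = (a_end - a_start + 1) + (b_end - b_start + 1) - inter
    return inter / union


def dmr_benchmark_config(seed: int, planted: bool = True) -> SimulationConfig:
    """18 pairs, ~50,000 CpGs, 50 planted DMRs (or none for the null)."""
    return SimulationConfig(
        seed=seed, chrom_length=12_000_000, n_background_clusters=1450,
        cluster_cpgs=(30, 40), n_dmrs=50 if planted else 0,
        n_hyper_drivers=0, n_hypo_drivers=0, n_lncrna_drivers=0,
        n_mirna_drivers=0, n_host_pairs=0, n_tf_groups=0,
        validation_cohorts=())


def dmr_benchmark(seed: int = 0, n_seeds: int = 20) -> dict:
    """DMR-caller sensitivity on planted truth (Jaccard >= 0.5, matching
    direction) and mean false calls on the matched null."""
    recovered, planted_n, false_calls, n_sites = [], [], [], []
    for rep in range(n_seeds):
        cfg = dmr_benchmark_config(rep_seed(seed, rep), planted=True)
        ann, truth = simulate_annotation(cfg)
        matrix = simulate_methylome(ann, truth, cfg).to_matrix()
        called = dmrmod.find_dmrs(matrix)
        rec = 0
        for r in truth.dmrs.itertuples():
            if any(d.interval.chrom == r.chrom and d.direction == r.direction
                   and jaccard(d.interval.start, d.interval.end, r.start,
                               r.end) >= 0.5 for d in called):
                rec += 1
        recovered.append(rec)
        planted_n.append(len(truth.dmrs))
        n_sites.append(matrix.n_sites)

        cfg0 = dmr_benchmark_config(rep_seed(seed, 1000 + rep), planted=False)
        ann0, truth0 = simulate_annotation(cfg0)
        matrix0 = simulate_methylome(ann0, truth0, cfg0).to_matrix()
        false_calls.append(len(dmrmod.find_dmrs(matrix0)))
    return {
        "sensitivity": float(np.sum(recovered) / np.sum(planted_n)),
        "mean_false_calls_null": float(np.mean(false_calls)),
        "recovered": recovered, "planted": planted_n,
        "false_calls": false_calls,
        "mean_sites": float(np.mean(n_sites)), "n_seeds": n_seeds,
    }


def study_benchmark(seed: int = 0, n_seeds: int = 20) -> dict:
    """Full-funnel benchmark at the default study conditions: DMR calling,
    chromatin-state enrichment of the hyper calls, driver discovery and
    two-cohort validation tiering, ncRNA drivers, and planted-TF motif
    rank."""
    out = {"driver_recall": [], "driver_false": [], "driver_called": [],
           "high_hyper": [], "high_hypo": [], "tf_top": [],
           "ncrna_recall": [], "poised_top": [], "n_called_dmrs": []}
    for rep in range(n_seeds):
        ds = simulate_dataset(SimulationConfig(seed=rep_seed(seed, rep)))
        called = dmrmod.find_dmrs(ds.matrix)
        out["n_called_dmrs"].append(len(called))
        genes = ds.annotation.genes
        coding = genes[genes["biotype"] == "coding"]

        # chromatin-state enrichment of hyper calls, first ESC epigenome
        hyper = dmrs_to_frame([d for d in called if d.direction == "hyper"])
        if len(hyper):
            G = sum(ds.annotation.chrom_sizes.values())
            seg = ds.annotation.states[ds.annotation.esc_ids[0]]
            enr = enrichment_table(hyper, seg, G)
            top_state = enr.loc[enr["F"].idxmax(), "state"]
            out["poised_top"].append(top_state == "TssBiv")

        # discovery + validation funnel
        de = drv.differential_expression(ds.expression)
        pairs = drv.pair_and_correlate(called, coding, ds.matrix,
                                       ds.expression)
        disc = drv.discovery_list(drv.select_best_per_gene(pairs), de)
        planted = set(ds.truth.drivers.loc[
            ds.truth.drivers["biotype"] == "coding", "gene_id"])
        got = set(disc["gene_id"])
        out["driver_recall"].append(len(got & planted) / len(planted))
        out["driver_false"].append(len(got - planted))
        out["driver_called"].append(len(got))
        vals = {name: drv.validate_on_probes(
            disc["gene_id"], c.betas, c.probe_positions, c.expr, coding)
            for name, c in ds.cohorts.items()}
        tiers = drv.tier_and_classify(disc, vals)
        high = tiers[tiers["tier"] == "high"]
        out["high_hyper"].append(int((high["direction"]
                                      == "hyper-driver").sum()))
        out["high_hypo"].append(int((high["direction"]
                                     == "hypo-driver").sum()))

        # ncRNA drivers reuse the same funnel
        nc_models = genes[genes["biotype"].isin(["lncRNA", "miRNA"])]
        from .ncrna import ncrna_drivers
        nc = ncrna_drivers(called, nc_models, ds.matrix, ds.expression)
        planted_nc = set(ds.truth.drivers.loc[
            ds.truth.drivers["biotype"] != "coding", "gene_id"])
        out["ncrna_recall"].append(
            len(set(nc["gene_id"]) & planted_nc) / max(len(planted_nc), 1))

        # planted-TF motif enrichment rank
        if ds.truth.planted_tf is not None and len(disc):
            enr_tf = tfmod.motif_enrichment(set(disc["dmr_id"]),
                                            dmrs_to_frame(called),
                                            ds.annotation.motifs)
            out["tf_top"].append(enr_tf.iloc[0]["tf"]
                                 == ds.truth.planted_tf)
    n_planted_hyper = SimulationConfig().n_hyper_drivers
    n_planted_hypo = SimulationConfig().n_hypo_drivers
    total_false = int(np.sum(out["driver_false"]))
    total_called = int(np.sum(out["driver_called"]))
    return {
        "mean_driver_recall": float(np.mean(out["driver_recall"])),
        "driver_fdr": total_false / max(total_called, 1),
        "mean_high_hyper": float(np.mean(out["high_hyper"])),
        "mean_high_hypo": float(np.mean(out["high_hypo"])),
        "planted_hyper": n_planted_hyper, "planted_hypo": n_planted_hypo,
        "tf_top_fraction": float(np.mean(out["tf_top"]))
        if out["tf_top"] else float("nan"),
        "poised_top_fraction": float(np.mean(out["poised_top"]))
        if out["poised_top"] else float("nan"),
        "mean_ncrna_recall": float(np.mean(out["ncrna_recall"])),
        "mean_called_dmrs": float(np.mean(out["n_called_dmrs"])),
        "per_seed": out, "n_seeds": n_seeds,
    }


def panel_benchmark(seed: int = 0, n_seeds: int = 20, n_markers: int = 8,
                    delta: float = 0.3, n_samples: int = 100) -> dict:
    """Test-split AUC of a planted marker panel versus a null panel."""
    planted_auc, null_auc = [], []
    half = n_samples // 2
    for rep in range(n_seeds):
        s = rep_seed(seed, rep)
        meth, labels = simulate_marker_cohort(
            n_tumor=half, n_normal=n_samples - half, n_markers=n_markers,
            delta=delta, seed=s)
        panel = [g for g in meth.index if g.startswith("MK")]
        planted_auc.append(
            evaluate_panel(meth, labels, panel, seed=s)["test_auc"])
        meth0, labels0 = simulate_marker_cohort(
            n_tumor=half, n_normal=n_samples - half, n_markers=n_markers,
            delta=0.0, seed=s + 1)
        panel0 = [g for g in meth0.index if g.startswith("MK")]
        null_auc.append(
            evaluate_panel(meth0, labels0, panel0, seed=s)["test_auc"])
    return {"mean_test_auc": float(np.mean(planted_auc)),
            "mean_null_auc": float(np.mean(null_auc)),
            "planted_auc": planted_auc, "null_auc": null_auc,
            "n_seeds": n_seeds, "n_samples": n_samples}
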