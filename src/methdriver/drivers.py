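"""Two-stage discovery-validation identification of methylation driver
genes.

Discovery pairs each called DMR with genes whose promoter (TSS +/- 2 kb) it
overlaps, keeps per gene the DMR with the most negative Spearman correlation
between region methylation and expression across all samples, and gates on
differential expression (paired t-test on log2(RPKM+1), BH FDR < 0.05,
|fold change| > 2) plus correlation strength (rho < -0.3, BH FDR < 0.05).
Validation repeats the correlation screen on array-style probe betas in
independent cohorts; genes validated in every cohort form the
high-confidence tier, in at least one the moderate tier.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import promoter_table
from .core import CpGMatrix, DesignError, ExpressionMatrix
from .dmr import DMR, dmrs_to_frame
from .methylome import _knn_impute_frame
from .stats import bh_adjust, spearman

__all__ = ["differential_expression", "pair_and_correlate",
           "select_best_per_gene", "discovery_list", "validate_on_probes",
           "tier_and_classify"]


def differential_expression(expr: ExpressionMatrix,
                            min_q90_rpkm: float = 1.0) -> pd.DataFrame:
    """Paired differential expression per gene.

    Genes whose 90th-quantile RPKM falls below ``min_q90_rpkm`` are dropped
    as unexpressed.  The paired t-test runs on log2(RPKM + 1); fold change
    is the ratio of mean tumor to mean normal RPKM on the linear scale.
    Zero-variance differences carry no evidence and get p = 1.
    """
    if expr.design is None:
        raise DesignError("differential expression needs a paired design")
    if len(expr.patients) < 3:
        raise ValueError("need at least 3 patient pairs")
    vals = expr.values
    q90 = vals.quantile(0.9, axis=1)
    kept = vals[q90 >= min_q90_rpkm]
    t = kept[expr.tumor_samples].to_numpy()
    n = kept[expr.normal_samples].to_numpy()
    lt, ln = np.log2(t + 1.0), np.log2(n + 1.0)
    d = lt - ln
    sd = d.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_rel(lt, ln, axis=1)
        pvals = np.where(sd == 0, 1.0, res.pvalue)
        mean_t = t.mean(axis=1)
        mean_n = n.mean(axis=1)
        fc = mean_t / mean_n
    out = pd.DataFrame({"mean_tumor": mean_t, "mean_normal": mean_n,
                        "fc": fc, "log2fc": np.log2(fc),
                        "p": pvals, "q": bh_adjust(pvals)},
                       index=kept.index)
    out.index.name = "gene_id"
    return out


def pair_and_correlate(dmrs: list[DMR] | pd.DataFrame, genes: pd.DataFrame,
                       matrix: CpGMatrix, expr: ExpressionMatrix,
                       flank: int = 2000,
                       min_fraction: float = 0.5) -> pd.DataFrame:
    """One row per (gene, promoter-overlapping DMR) pair with the Spearman
    correlation between per-sample DMR methylation (mean rate over member
    CpGs) and gene expression across all samples jointly, BH-adjusted over
    all pairs.  Pairs with degenerate (constant) methylation are dropped
    with a warning; genes absent from the expression matrix are skipped."""
    dmr_frame = dmrs_to_frame(dmrs) if isinstance(dmrs, list) else dmrs
    promoters = promoter_table(genes, flank=flank)
    meth = matrix.region_methylation(
        dmr_frame.set_index("dmr_id")[["chrom", "start", "end"]])
    samples = [s for s in matrix.rates.columns if s in expr.values.columns]
    rows = []
    for _, d in dmr_frame.iterrows():
        need = min_fraction * (d["end"] - d["start"] + 1)
        hits = promoters[(promoters["chrom"] == d["chrom"])
                         & (np.minimum(promoters["end"], d["end"])
                            - np.maximum(promoters["start"], d["start"]) + 1
                            >= need)]
        for g in hits["gene_id"]:
            if g not in expr.values.index:
                continue
            m = meth.loc[d["dmr_id"], samples].to_numpy(dtype=float)
            e = np.log2(expr.values.loc[g, samples]
                        .to_numpy(dtype=float) + 1.0)
            rho, p = spearman(m, e)
            if np.isnan(rho):
                warnings.warn(f"degenerate methylation/expression for pair "
                              f"({g}, {d['dmr_id']}); pair dropped",
                              stacklevel=2)
                continue
            rows.append({"gene_id": g, "dmr_id": d["dmr_id"],
                         "chrom": d["chrom"], "start": d["start"],
                         "end": d["end"], "delta": d["delta"],
                         "rho": rho, "p": p})
    pairs = pd.DataFrame(rows, columns=["gene_id", "dmr_id", "chrom",
                                        "start", "end", "delta", "rho", "p"])
    pairs["q"] = bh_adjust(pairs["p"]) if len(pairs) else []
    return pairs


def select_best_per_gene(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per gene, the pair with the most negative rho (the most plausible
    silencing event); ties by smaller p, then leftmost DMR."""
    if len(pairs) == 0:
        return pairs
    ordered = pairs.sort_values(["gene_id", "rho", "p", "chrom", "start"],
                                kind="stable")
    return ordered.groupby("gene_id", as_index=False).first()


def discovery_list(best_pairs: pd.DataFrame, de_table: pd.DataFrame,
                   rho_max: float = -0.3, q_max: float = 0.05,
                   de_q: float = 0.05, min_fc: float = 2.0) -> pd.DataFrame:
    """Primary driver list: differentially expressed (q < de_q and fold
    change > min_fc or < 1/min_fc) genes whose best promoter DMR shows
    rho < rho_max with pair q < q_max.  Direction: hyper-driver = methylation
    gain with downregulation, hypo-driver = loss with upregulation."""
    if len(best_pairs) == 0:
        return best_pairs.assign(direction=pd.Series(dtype=str))
    merged = best_pairs.merge(de_table.reset_index(), on="gene_id",
                              how="inner")
    keep = ((merged["q_y"] < de_q)
            & ((merged["fc"] > min_fc) | (merged["fc"] < 1.0 / min_fc))
            & (merged["rho"] < rho_max)
            & (merged["q_x"] < q_max))
    out = merged[keep].rename(columns={"q_x": "q_pair", "q_y": "q_de",
                                       "p_x": "p_pair", "p_y": "p_de"})
    direction = np.where((out["delta"] > 0) & (out["log2fc"] < 0),
                         "hyper-driver",
                         np.where((out["delta"] < 0) & (out["log2fc"] > 0),
                                  "hypo-driver", "inconsistent"))
    out = out.assign(direction=direction)
    return out.reset_index(drop=True)


def validate_on_probes(primary_genes, betas: pd.DataFrame,
                       probe_positions: pd.DataFrame, expr: pd.DataFrame,
                       genes: pd.DataFrame, flank: int = 2000,
                       max_missing: float = 0.10, knn_k: int = 10,
                       rho_max: float = -0.3,
                       q_max: float = 0.05) -> pd.DataFrame:
    """Validation screen on one array-style cohort.

    Probes with more than ``max_missing`` missing betas are discarded and
    the rest KNN-imputed in probe space.  Each remaining probe is assigned
    to gene promoters containing its position; per gene the probe with the
    most negative Spearman rho against expression (log2(RPKM+1), all cohort
    samples jointly) is kept, and the gene validates when rho < rho_max
    with BH q < q_max across the tested genes.  Genes without any promoter
    probe are reported untestable (excluded from the BH family)."""
    shared = [s for s in betas.columns if s in expr.columns]
    if not shared:
        raise DesignError("validation cohort: no shared samples between "
                          "betas and expression")
    betas = betas[shared]
    frac_missing = betas.isna().mean(axis=1)
    betas = betas[frac_missing <= max_missing]
    if betas.isna().to_numpy().any():
        betas = _knn_impute_frame(betas, k=knn_k)
    promoters = promoter_table(genes, flank=flank).set_index("gene_id")
    pos_map = probe_positions.set_index("probe_id")
    rows = []
    for g in primary_genes:
        if g not in promoters.index:
            rows.append({"gene_id": g, "testable": False})
            continue
        pr = promoters.loc[g]
        in_prom = pos_map[(pos_map["chrom"] == pr["chrom"])
                          & (pos_map["pos"] >= pr["start"])
                          & (pos_map["pos"] <= pr["end"])]
        probe_ids = [p for p in in_prom.index if p in betas.index]
        if not probe_ids or g not in expr.index:
            rows.append({"gene_id": g, "testable": False})
            continue
        e = np.log2(expr.loc[g, shared].to_numpy(dtype=float) + 1.0)
        best = None
        for pid in probe_ids:
            rho, p = spearman(betas.loc[pid].to_numpy(dtype=float), e)
            if np.isnan(rho):
                continue
            if best is None or rho < best[1]:
                best = (pid, rho, p)
        if best is None:
            rows.append({"gene_id": g, "testable": False})
            continue
        rows.append({"gene_id": g, "testable": True, "probe_id": best[0],
                     "rho": best[1], "p": best[2]})
    out = pd.DataFrame(rows)
    if "rho" not in out.columns:
        out["rho"] = np.nan
        out["p"] = np.nan
    out["q"] = bh_adjust(out["p"])
    out["validated"] = (out["testable"].fillna(False)
                        & (out["rho"] < rho_max) & (out["q"] < q_max))
    return out


def tier_and_classify(discovery: pd.DataFrame,
                      validations: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Confidence tiers from the validation cohorts: ``high`` = validated in
    all cohorts, ``moderate`` = in at least one, ``primary`` = discovery
    only.  Direction carries over from discovery; an inconsistent direction
    (delta sign against expression sign) is flagged rather than silently
    kept."""
    if len(validations) < 2:
        warnings.warn("high tier nominally requires >= 2 validation cohorts",
                      stacklevel=2)
    val_sets = {name: set(v.loc[v["validated"], "gene_id"])
                for name, v in validations.items()}
    untestable = {name: set(v.loc[~v["testable"].astype(bool), "gene_id"])
                  for name, v in validations.items()}
    rows = []
    for _, r in discovery.iterrows():
        g = r["gene_id"]
        supported = [name for name, s in val_sets.items() if g in s]
        n_val = len(supported)
        tier = ("high" if n_val == len(validations) and len(validations) > 0
                else "moderate" if n_val >= 1 else "primary")
        rows.append({"gene_id": g, "direction": r["direction"],
                     "tier": tier, "n_cohorts": n_val,
                     "cohorts": ",".join(supported),
                     "untestable_in": ",".join(
                         n for n, s in untestable.items() if g in s),
                     "dmr_id": r["dmr_id"], "rho": r["rho"],
                     "q_pair": r["q_pair"], "fc": r["fc"],
                     "q_de": r["q_de"],
                     "flag": "inconsistent-direction"
                     if r["direction"] == "inconsistent" else ""})
    return pd.DataFrame(rows)
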