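"""Noncoding-RNA analyses: the lncRNA coding-potential filter cascade,
miRNA RPM normalization, metagene methylation profiles, ncRNA driver calls
and ncRNA/host-gene co-regulation, plus guilt-by-association co-expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CpGMatrix, ExpressionMatrix
from .dmr import DMR
from .drivers import (differential_expression, discovery_list,
                      pair_and_correlate, select_best_per_gene)
from .stats import bh_adjust, spearman

__all__ = ["filter_lncrna", "mirna_normalize", "metagene_profile",
           "MetageneProfile", "ncrna_drivers", "host_coregulation",
           "guilt_by_association", "CASCADE_RULES"]

#: Cascade rule names in application order.
CASCADE_RULES = ("single_exon_or_short", "high_phylocsf",
                 "cbl_positive_long_orf", "cbl_zero_orf50", "blastx_hit")


def _rule_masks(records: pd.DataFrame) -> dict[str, pd.Series]:
    """Per-rule drop predicates (independent of application order)."""
    phylo = records["phylocsf"]
    cbl = records["cbl"]
    orf = records["orf_aa"]
    evalue = records["blastx_median_evalue"]
    return {
        "single_exon_or_short": (records["exon_count"] == 1)
        | (records["length_bp"] < 160),
        "high_phylocsf": phylo > 50,                      # strictly greater
        "cbl_positive_long_orf": (cbl > 0) & (orf > 150),
        "cbl_zero_orf50": (cbl == 0) & (orf > 50),
        # missing blastx median = no protein hit at all = keep
        "blastx_hit": evalue.notna() & (evalue < 1e-18),
    }


def filter_lncrna(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Coding-potential filter cascade for candidate lncRNA transcripts.

    Rules, applied in order to the transcripts still standing: (1) single
    exon or length < 160 bp; (2) PhyloCSF > 50; (3) complete branch length
    (CBL) > 0 with an ORF > 150 aa; (4) CBL = 0 (poor alignment) with an
    ORF > 50 aa; (5) median blastx E-value < 1e-18.  Because each rule is an
    independent predicate, the surviving set does not depend on rule order
    (only the per-rule removal counts do)."""
    masks = _rule_masks(records)
    remaining = records
    removed = {}
    for rule in CASCADE_RULES:
        drop = masks[rule].loc[remaining.index]
        removed[rule] = int(drop.sum())
        remaining = remaining[~drop]
    return remaining, removed


def mirna_normalize(counts: pd.DataFrame, library_sizes: pd.Series
                    ) -> pd.DataFrame:
    """miRNA quantification: reads per million mapped reads, then
    ``log2(RPM + 1)``."""
    sizes = library_sizes.reindex(counts.columns)
    if sizes.isna().any() or (sizes <= 0).any():
        raise ValueError("every sample needs a positive library size")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rpm = counts / sizes * 1e6
    return np.log2(rpm + 1.0)


@dataclass
class MetageneProfile:
    """Mean methylation across scaled gene bodies and absolute flanks.

    ``bins`` has one row per bin with region (upstream/body/downstream),
    bin index within region and a relative coordinate; one column of means
    per sample group.  Flanks use 1 kb sliding windows at 100 bp steps over
    +/- ``flank`` bp (41 windows per side at the defaults); the body is cut
    into ``body_bins`` equal relative bins.  Minus-strand genes are flipped
    so the axis always reads TSS to TES."""
    bins: pd.DataFrame
    n_genes_used: int
    n_genes_excluded: int


def metagene_profile(matrix: CpGMatrix, genes: pd.DataFrame,
                     groups: dict[str, list] | None = None,
                     flank: int = 5000, window: int = 1000, step: int = 100,
                     body_bins: int = 40) -> MetageneProfile:
    if groups is None:
        groups = {"tumor": matrix.tumor_samples,
                  "normal": matrix.normal_samples}
    n_flank = (flank - window) // step + 1
    chroms = matrix.chroms
    positions = matrix.positions
    group_vals = {g: matrix.rates[cols].to_numpy() for g, cols in
                  groups.items()}

    n_bins_total = 2 * n_flank + body_bins
    sums = {g: np.zeros(n_bins_total) for g in groups}
    counts = {g: np.zeros(n_bins_total) for g in groups}
    used = excluded = 0
    for _, gene in genes.iterrows():
        length = gene["end"] - gene["start"] + 1
        if length < window:
            excluded += 1
            continue
        used += 1
        on = chroms == gene["chrom"]
        p = positions[on]
        tss = gene["start"] if gene["strand"] == "+" else gene["end"]
        tes = gene["end"] if gene["strand"] == "+" else gene["start"]
        sign = 1 if gene["strand"] == "+" else -1
        for g, vals in group_vals.items():
            v = vals[on]
            with np.errstate(invalid="ignore"):
                site_mean = np.nanmean(v, axis=1)
            # upstream flank windows (most distal first)
            for i in range(n_flank):
                w_start = tss - sign * (flank - i * step)
                w_end = w_start + sign * (window - 1)
                lo, hi = sorted((w_start, w_end))
                sel = site_mean[(p >= lo) & (p <= hi)]
                sel = sel[~np.isnan(sel)]
                if sel.size:
                    sums[g][i] += sel.mean()
                    counts[g][i] += 1
            # body bins
            lo, hi = sorted((tss, tes))
            in_body = (p >= lo) & (p <= hi)
            bp = p[in_body]
            bv = site_mean[in_body]
            rel = (bp - tss) * sign / length
            bin_idx = np.clip((rel * body_bins).astype(int), 0, body_bins - 1)
            for b in range(body_bins):
                sel = bv[bin_idx == b]
                sel = sel[~np.isnan(sel)]
                if sel.size:
                    sums[g][n_flank + b] += sel.mean()
                    counts[g][n_flank + b] += 1
            # downstream flank windows
            for i in range(n_flank):
                w_start = tes + sign * (1 + i * step)
                w_end = w_start + sign * (window - 1)
                lo, hi = sorted((w_start, w_end))
                sel = site_mean[(p >= lo) & (p <= hi)]
                sel = sel[~np.isnan(sel)]
                if sel.size:
                    sums[g][n_flank + body_bins + i] += sel.mean()
                    counts[g][n_flank + body_bins + i] += 1
    region = (["upstream"] * n_flank + ["body"] * body_bins
              + ["downstream"] * n_flank)
    rel_coord = ([-(flank - i * step) / 1000 for i in range(n_flank)]
                 + [(b + 0.5) / body_bins for b in range(body_bins)]
                 + [(window + i * step) / 1000 for i in range(n_flank)])
    bins = pd.DataFrame({"region": region, "rel_coord": rel_coord})
    for g in groups:
        with np.errstate(invalid="ignore"):
            bins[g] = np.where(counts[g] > 0, sums[g] / counts[g], np.nan)
    return MetageneProfile(bins=bins, n_genes_used=used,
                           n_genes_excluded=excluded)


def ncrna_drivers(dmrs: list[DMR] | pd.DataFrame, ncrna_models: pd.DataFrame,
                  matrix: CpGMatrix, expr: ExpressionMatrix,
                  rho_max: float = -0.3, q_max: float = 0.05,
                  de_q: float = 0.05, min_fc: float = 2.0) -> pd.DataFrame:
    """Methylation-driver ncRNAs: the coding discovery pipeline applied to
    lncRNA/miRNA models (promoters defined identically, TSS +/- 2 kb) with
    identical thresholds; the biotype is carried through."""
    pairs = pair_and_correlate(dmrs, ncrna_models, matrix, expr)
    best = select_best_per_gene(pairs)
    nc_expr = ExpressionMatrix(
        expr.values.loc[[g for g in ncrna_models["gene_id"]
                         if g in expr.values.index]], expr.design)
    de = differential_expression(nc_expr)
    out = discovery_list(best, de, rho_max=rho_max, q_max=q_max, de_q=de_q,
                         min_fc=min_fc)
    biotype = ncrna_models.set_index("gene_id")["biotype"]
    out["biotype"] = [biotype.get(g) for g in out["gene_id"]]
    return out


def host_coregulation(ncrna_calls: pd.DataFrame, gene_calls: pd.DataFrame,
                      ncrna_models: pd.DataFrame) -> pd.DataFrame:
    """ncRNA/host-gene pairs co-regulated by the same promoter methylation
    event: both are driver calls and their calls share a common promoter
    DMR id."""
    hosts = ncrna_models.set_index("gene_id")["host_gene"]
    gene_dmr = dict(zip(gene_calls["gene_id"], gene_calls["dmr_id"]))
    rows = []
    for _, r in ncrna_calls.iterrows():
        host = hosts.get(r["gene_id"])
        if pd.isna(host) or host not in gene_dmr:
            continue
        if gene_dmr[host] == r["dmr_id"]:
            rows.append({"ncrna_id": r["gene_id"], "host_gene": host,
                         "dmr_id": r["dmr_id"],
                         "direction": r["direction"]})
    return pd.DataFrame(rows, columns=["ncrna_id", "host_gene", "dmr_id",
                                       "direction"])


def guilt_by_association(target_expr: pd.Series, coding_expr: pd.DataFrame,
                         rho_min: float = 0.5,
                         q_max: float = 0.01) -> pd.DataFrame:
    """Coding genes significantly co-expressed with a target transcript:
    |rho| > rho_min (strict) and BH q < q_max over all tested genes."""
    shared = [s for s in target_expr.index if s in coding_expr.columns]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    t = target_expr[shared].to_numpy(dtype=float)
    rows = []
    for g, row in coding_expr[shared].iterrows():
        rho, p = spearman(t, row.to_numpy(dtype=float))
        rows.append({"gene_id": g, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    out["coexpressed"] = (np.abs(out["rho"]) > rho_min) & (out["q"] < q_max)
    return out
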