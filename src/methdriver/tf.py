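"""Transcription-factor motif analysis in DMRs: hypergeometric motif
enrichment against the full DMR background, TF-target expression
correlation, the activity score ``y = rho * log2(fold change)``, CpG content
of motifs and flanks, and the hyper-versus-hypo direction comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact, hypergeom_tail, spearman

__all__ = ["motif_enrichment", "tf_target_correlation", "activity_score",
           "average_activity", "activity_matrix", "motif_cpg_report",
           "direction_comparison"]


def _dmrs_with_hit(dmr_frame: pd.DataFrame, hits: pd.DataFrame) -> set:
    """ids of DMRs containing at least one motif hit (region-level count)."""
    out = set()
    for chrom, grp in hits.groupby("chrom"):
        sub = dmr_frame[dmr_frame["chrom"] == chrom]
        if len(sub) == 0:
            continue
        for _, d in sub.iterrows():
            if ((grp["start"] <= d["end"])
                    & (grp["end"] >= d["start"])).any():
                out.add(d["dmr_id"])
    return out


def motif_enrichment(interest_ids, all_dmrs: pd.DataFrame,
                     motif_hits: pd.DataFrame) -> pd.DataFrame:
    """Per-TF hypergeometric enrichment of motif hits in a DMR set of
    interest against the full DMR background.

    For each TF group: N = background DMRs, K = interest DMRs, n =
    background DMRs containing >= 1 hit, k = interest DMRs containing >= 1
    hit; p = P(X >= k) with X ~ Hypergeometric(N, K, n), BH-adjusted across
    TFs.  The interest set must be a subset of the background."""
    interest = set(interest_ids)
    background = set(all_dmrs["dmr_id"])
    if not interest <= background:
        raise ValueError("interest DMRs must be a subset of the background")
    N, K = len(background), len(interest)
    rows = []
    for tf, hits in motif_hits.groupby("tf"):
        with_hit = _dmrs_with_hit(all_dmrs, hits)
        n = len(with_hit)
        k = len(with_hit & interest)
        p = hypergeom_tail(N, K, n, k)
        rows.append({"tf": tf, "N": N, "K": K, "n": n, "k": k, "p": p})
    out = pd.DataFrame(rows).sort_values("p", kind="stable")
    out["q"] = bh_adjust(out["p"])
    return out.reset_index(drop=True)


def tf_target_correlation(tf_expr: pd.DataFrame, target_expr: pd.DataFrame,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation between each TF's expression and each target
    gene's expression across shared samples, BH-adjusted over all pairs.
    Degenerate (constant) vectors drop the pair."""
    shared = [s for s in tf_expr.columns if s in target_expr.columns]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    rows = []
    for tf, trow in tf_expr[shared].iterrows():
        for g, grow in target_expr[shared].iterrows():
            rho, p = spearman(trow.to_numpy(dtype=float),
                              grow.to_numpy(dtype=float))
            if np.isnan(rho):
                continue
            rows.append({"tf": tf, "gene_id": g, "rho": rho, "p": p})
    out = pd.DataFrame(rows, columns=["tf", "gene_id", "rho", "p"])
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    out["significant"] = out["q"] < alpha if len(out) else []
    return out


def activity_score(rho: float, fc: float) -> float:
    """``y = rho * log2(fc)`` where rho correlates DMR methylation with
    target expression and fc is the target's tumor/normal fold change.
    Positive y marks concordant dysregulation (e.g. methylation-silenced
    targets: rho < 0 with fc < 1)."""
    if fc <= 0:
        raise ValueError("fold change must be positive")
    return float(rho * np.log2(fc))


def average_activity(site_scores) -> float:
    """Mean per-site activity score for a TF with multiple binding sites in
    the target's DMR."""
    scores = np.asarray(list(site_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("no per-site scores to average")
    return float(scores.mean())


def activity_matrix(pairs: pd.DataFrame) -> pd.DataFrame:
    """TF-by-target matrix of average activity scores from a long table
    with columns tf, gene_id, y (one row per binding site)."""
    return pairs.groupby(["tf", "gene_id"])["y"].mean().unstack()


def motif_cpg_report(motif_hits: pd.DataFrame, cpg_positions: pd.DataFrame,
                     flank: int = 100) -> pd.DataFrame:
    """Per motif hit, CpGs strictly inside the motif interval and CpGs in
    the +/- ``flank`` bp side windows (side-window endpoints inclusive, so a
    CpG exactly ``flank`` bp away still counts)."""
    rows = []
    for i, h in motif_hits.iterrows():
        p = cpg_positions.loc[cpg_positions["chrom"] == h["chrom"],
                              "pos"].to_numpy()
        inside = int(((p >= h["start"]) & (p <= h["end"])).sum())
        in_flank = int((((p >= h["start"] - flank) & (p <= h["start"] - 1))
                        | ((p >= h["end"] + 1)
                           & (p <= h["end"] + flank))).sum())
        rows.append({"tf": h["tf"], "chrom": h["chrom"], "start": h["start"],
                     "end": h["end"], "cpg_inside": inside,
                     "cpg_flank": in_flank})
    return pd.DataFrame(rows, columns=["tf", "chrom", "start", "end",
                                       "cpg_inside", "cpg_flank"])


def direction_comparison(enriched_hyper: int, enriched_hypo: int,
                         total_tfs: int) -> dict:
    """Two-sided Fisher exact test comparing how many TF groups are
    enriched in hyper- versus hypomethylated regions; the 2x2 table
    (enriched vs not, per direction) is returned explicitly."""
    if enriched_hyper > total_tfs or enriched_hypo > total_tfs:
        raise ValueError("enriched counts exceed the number of TF groups")
    table = [[enriched_hyper, total_tfs - enriched_hyper],
             [enriched_hypo, total_tfs - enriched_hypo]]
    return {"table": table, "p": fisher_exact(table)}
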