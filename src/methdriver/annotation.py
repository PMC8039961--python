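"""Annotation of DMRs against promoters, CpG islands and multi-epigenome
chromatin states, with fold-enrichment and normalized enrichment scoring.

A feature is annotated to a DMR when it covers at least half of the DMR's
bases; a chromatin state is "ESC-recurrent" when it is annotated in at
least half of the available embryonic-stem-cell epigenomes.  Fold
enrichment for a state follows the odds-ratio form
``F = (O/G) / ((D/G) * (S/G)) = O * G / (D * S)`` over base counts, and the
normalized score ``E_i = F_i / sum_j F_j`` compares states on a common
probability scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenomicInterval, gene_tss

__all__ = ["STATES15", "POISED_STATES", "ACTIVE_STATES", "annotate_dmr",
           "promoter_of", "promoter_table", "esc_recurrent_state",
           "fold_enrichment", "normalized_enrichment", "enrichment_table",
           "classify_hyper_dmr", "subtype_summary", "merge_intervals",
           "total_bases", "overlap_bases"]

#: Canonical 15-state chromatin alphabet (Roadmap core model mnemonics);
#: list order is also the tie-break order for recurrent-state assignment.
STATES15 = ["TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh",
            "ZNF/Rpts", "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC",
            "ReprPCWk", "Quies"]

#: Bivalent ("poised") and active promoter state groups.
POISED_STATES = frozenset({"TssBiv", "BivFlnk"})
ACTIVE_STATES = frozenset({"TssA", "TssAFlnk"})


# ---------------------------------------------------------------------------
# interval set arithmetic (1-based inclusive throughout)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals as a sorted, disjoint set (adjacent intervals are
    merged)."""
    if len(intervals) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                out.append([chrom, cur_s, cur_e])
                cur_s, cur_e = s, e
        out.append([chrom, cur_s, cur_e])
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def total_bases(intervals: pd.DataFrame) -> int:
    merged = merge_intervals(intervals)
    if len(merged) == 0:
        return 0
    return int((merged["end"] - merged["start"] + 1).sum())


def overlap_bases(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Number of bases in the intersection of two interval sets."""
    am = merge_intervals(a)
    bm = merge_intervals(b)
    total = 0
    for chrom, agrp in am.groupby("chrom"):
        bgrp = bm[bm["chrom"] == chrom]
        if len(bgrp) == 0:
            continue
        bs = bgrp["start"].to_numpy()
        be = bgrp["end"].to_numpy()
        for s, e in zip(agrp["start"], agrp["end"]):
            lo = np.searchsorted(be, s, side="left")
            hi = np.searchsorted(bs, e, side="right")
            if hi > lo:
                total += int(np.sum(np.minimum(e, be[lo:hi])
                                    - np.maximum(s, bs[lo:hi]) + 1))
    return total


def _interval_frame(interval: GenomicInterval) -> pd.DataFrame:
    return pd.DataFrame({"chrom": [interval.chrom],
                         "start": [interval.start], "end": [interval.end]})


# ---------------------------------------------------------------------------
# annotation rules
# ---------------------------------------------------------------------------

def annotate_dmr(dmr_interval: GenomicInterval, features: pd.DataFrame,
                 min_fraction: float = 0.5,
                 label_col: str | None = None) -> list:
    """Labels of features covering at least ``min_fraction`` of the DMR's
    bases (boundary inclusive).  ``features`` has chrom/start/end and
    optionally a label column; without one, row indices are returned.
    Feature rows sharing a label are unioned before the coverage test."""
    need = min_fraction * dmr_interval.length
    dmr_frame = _interval_frame(dmr_interval)
    labels = []
    if label_col is None:
        groups = [(idx, features.loc[[idx]]) for idx in features.index]
    else:
        groups = list(features.groupby(label_col, sort=False))
    for label, grp in groups:
        if overlap_bases(dmr_frame, grp) >= need:
            labels.append(label)
    return labels


def promoter_of(gene: pd.Series, flank: int = 2000) -> GenomicInterval:
    """Promoter = TSS +/- ``flank`` (strand-aware TSS), clipped at the
    chromosome start; 4,001 bp when unclipped."""
    tss = int(gene["start"] if gene["strand"] == "+" else gene["end"])
    return GenomicInterval(gene["chrom"], max(1, tss - flank), tss + flank)


def promoter_table(genes: pd.DataFrame, flank: int = 2000) -> pd.DataFrame:
    """Promoter intervals for a gene-model table, indexed like it."""
    tss = gene_tss(genes)
    return pd.DataFrame({"gene_id": genes["gene_id"],
                         "chrom": genes["chrom"],
                         "start": np.maximum(1, tss - flank),
                         "end": tss + flank}, index=genes.index)


def esc_recurrent_state(dmr_interval: GenomicInterval,
                        esc_segmentations: dict,
                        min_fraction: float = 0.5) -> str | None:
    """State recurrently annotated to the DMR in at least half of the
    available ESC epigenomes (ceiling for odd counts); the most recurrent
    state wins, ties broken by canonical state order."""
    if not esc_segmentations:
        raise ValueError("need at least one ESC segmentation")
    n = len(esc_segmentations)
    need = int(np.ceil(n / 2))
    counts: dict[str, int] = {}
    for seg in esc_segmentations.values():
        sub = seg[seg["chrom"] == dmr_interval.chrom]
        for state in annotate_dmr(dmr_interval, sub, min_fraction,
                                  label_col="state"):
            counts[state] = counts.get(state, 0) + 1
    eligible = {s: c for s, c in counts.items() if c >= need}
    if not eligible:
        return None
    order = {s: i for i, s in enumerate(STATES15)}
    return min(eligible, key=lambda s: (-eligible[s],
                                        order.get(s, len(STATES15))))


# ---------------------------------------------------------------------------
# enrichment scores
# ---------------------------------------------------------------------------

def fold_enrichment(dmr_intervals: pd.DataFrame, state_intervals: pd.DataFrame,
                    genome_size: int) -> float:
    """``F = O * G / (D * S)`` over base counts: the observed joint overlap
    against the product of marginals.  F = 0 when the overlap is empty;
    an empty DMR set or empty state is undefined and raises."""
    D = total_bases(dmr_intervals)
    S = total_bases(state_intervals)
    if D == 0 or S == 0:
        raise ValueError("fold enrichment undefined for an empty DMR set or "
                         "empty state")
    O = overlap_bases(dmr_intervals, state_intervals)
    return float(O) * float(genome_size) / (float(D) * float(S))


def normalized_enrichment(folds) -> np.ndarray:
    """``E_i = F_i / sum_j F_j``; a probability vector over states."""
    f = np.asarray(folds, dtype=float)
    if (f < 0).any():
        raise ValueError("fold enrichments must be non-negative")
    s = f.sum()
    if s == 0:
        raise ValueError("all fold enrichments are zero; E undefined")
    return f / s


def enrichment_table(dmr_intervals: pd.DataFrame, segmentation: pd.DataFrame,
                     genome_size: int,
                     states: list[str] = STATES15) -> pd.DataFrame:
    """Per-state fold enrichment F and normalized score E for one
    epigenome's segmentation."""
    folds = []
    for state in states:
        sub = segmentation[segmentation["state"] == state]
        if total_bases(sub) == 0:
            folds.append(0.0)
        else:
            folds.append(fold_enrichment(dmr_intervals, sub, genome_size))
    E = normalized_enrichment(folds)
    return pd.DataFrame({"state": states, "F": folds, "E": E})


# ---------------------------------------------------------------------------
# hyper-DMR subtypes
# ---------------------------------------------------------------------------

def classify_hyper_dmr(dmr_interval: GenomicInterval,
                       promoters: pd.DataFrame, esc_segmentations: dict,
                       poised=POISED_STATES, active=ACTIVE_STATES,
                       min_fraction: float = 0.5) -> str:
    """Subtype of a hypermethylated DMR: ``poised-promoter`` or
    ``active-promoter`` when it sits in a promoter whose ESC-recurrent state
    belongs to the respective group, ``promoter-other`` for promoter DMRs
    with another (or no) recurrent state, else ``non-promoter``."""
    in_promoter = len(annotate_dmr(dmr_interval, promoters, min_fraction,
                                   label_col="gene_id")) > 0
    if not in_promoter:
        return "non-promoter"
    state = esc_recurrent_state(dmr_interval, esc_segmentations, min_fraction)
    if state in poised:
        return "poised-promoter"
    if state in active:
        return "active-promoter"
    return "promoter-other"


def subtype_summary(subtypes: pd.Series) -> pd.DataFrame:
    """Counts and percentages of the full hyper-DMR set per subtype."""
    counts = subtypes.value_counts()
    total = int(counts.sum())
    return pd.DataFrame({"count": counts,
                         "percent": 100.0 * counts / total})
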