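"""Differentially methylated region calling for paired tumor/normal data.

Candidate regions come from a recursive binary segmentation of the per-CpG
mean paired-difference signal (objective ``|mean delta| * sqrt(length)``,
CBS-flavored); each candidate is then tested with the exact paired Wilcoxon
signed-rank test on per-patient region means, and the final call set is
gated by the three thresholds that define a DMR here: at least ``min_cpg``
member CpGs, at least ``min_delta`` absolute methylation difference, and
Benjamini-Hochberg FDR below ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CpGMatrix, GenomicInterval
from .stats import bh_adjust, wilcoxon_signed_rank

__all__ = ["DMR", "Candidate", "presegment", "segment", "test_candidate",
           "call_dmrs", "find_dmrs", "summarize", "dmrs_to_frame"]


@dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    n_cpg: int
    delta: float
    p_value: float
    q_value: float
    direction: str

    @property
    def dmr_id(self) -> str:
        return str(self.interval)


@dataclass(frozen=True)
class Candidate:
    """A segmentation candidate: half-open site-index range into the sorted
    site arrays of the matrix it came from."""
    chrom: str
    start: int
    end: int
    lo: int            # first site index (inclusive)
    hi: int            # past-the-end site index
    mean_diff: float

    @property
    def n_cpg(self) -> int:
        return self.hi - self.lo


def presegment(chroms: np.ndarray, positions: np.ndarray,
               max_gap_bp: int = 300,
               min_cpg: int = 10) -> list[tuple[int, int]]:
    """Split sorted CpG sites into windows wherever consecutive CpGs are
    more than ``max_gap_bp`` apart or the chromosome changes; windows with
    fewer than ``min_cpg`` sites are discarded.  Returns half-open index
    ranges."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    n = positions.size
    if n == 0:
        return []
    same_chrom = chroms[1:] == chroms[:-1]
    gaps = np.diff(positions)
    if np.any(same_chrom & (gaps <= 0)):
        raise ValueError("sites must be sorted by (chrom, pos)")
    breaks = np.where(~same_chrom | (gaps > max_gap_bp))[0] + 1
    bounds = np.concatenate([[0], breaks, [n]])
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])
            if b - a >= min_cpg]


def _best_subsegment(d: np.ndarray, min_cpg: int,
                     min_delta: float) -> tuple[int, int] | None:
    """Sub-array maximizing |mean| * sqrt(len) subject to len >= min_cpg and
    |mean| >= min_delta; ties go to the leftmost start, then the longest."""
    n = d.size
    if n < min_cpg:
        return None
    csum = np.concatenate([[0.0], np.cumsum(d)])
    best = None  # (objective, start, length)
    for length in range(min_cpg, n + 1):
        means = (csum[length:] - csum[:-length]) / length
        obj = np.abs(means) * np.sqrt(length)
        ok = np.abs(means) >= min_delta
        if not ok.any():
            continue
        obj = np.where(ok, obj, -np.inf)
        i = int(np.argmax(obj))
        cand = (float(obj[i]), i, length)
        if best is None:
            best = cand
            continue
        if cand[0] > best[0] + 1e-12:
            best = cand
        elif abs(cand[0] - best[0]) <= 1e-12:
            if cand[1] < best[1] or (cand[1] == best[1]
                                     and cand[2] > best[2]):
                best = cand
    if best is None:
        return None
    return best[1], best[1] + best[2]


def segment(diff: np.ndarray, positions: np.ndarray, chrom: str,
            min_cpg: int = 10, min_delta: float = 0.10,
            offset: int = 0) -> list[Candidate]:
    """Recursive binary segmentation of one pre-segmentation window.

    The maximal-objective sub-segment is emitted and its flanks are
    segmented recursively, so the output is a set of non-overlapping
    candidates each satisfying the count and delta gates."""
    d = np.asarray(diff, dtype=float)
    found = _best_subsegment(np.nan_to_num(d, nan=0.0), min_cpg, min_delta)
    if found is None:
        return []
    i, j = found
    with np.errstate(invalid="ignore"):
        mean_diff = float(np.nanmean(d[i:j]))
    here = Candidate(chrom=chrom, start=int(positions[i]),
                     end=int(positions[j - 1]), lo=offset + i, hi=offset + j,
                     mean_diff=mean_diff)
    left = segment(d[:i], positions[:i], chrom, min_cpg, min_delta, offset)
    right = segment(d[j:], positions[j:], chrom, min_cpg, min_delta,
                    offset + j)
    return left + [here] + right


def test_candidate(candidate: Candidate, matrix: CpGMatrix) -> float:
    """Exact two-sided paired Wilcoxon signed-rank p-value on per-patient
    mean tumor minus mean normal rate over the candidate's member CpGs."""
    sl = slice(candidate.lo, candidate.hi)
    t = matrix.rates[matrix.tumor_samples].to_numpy()[sl]
    n = matrix.rates[matrix.normal_samples].to_numpy()[sl]
    with np.errstate(invalid="ignore"):
        diffs = np.nanmean(t, axis=0) - np.nanmean(n, axis=0)
    return wilcoxon_signed_rank(diffs)


def _candidate_delta(candidate: Candidate, matrix: CpGMatrix) -> float:
    sl = slice(candidate.lo, candidate.hi)
    t = matrix.rates[matrix.tumor_samples].to_numpy()[sl]
    n = matrix.rates[matrix.normal_samples].to_numpy()[sl]
    with np.errstate(invalid="ignore"):
        diffs = np.nanmean(t, axis=0) - np.nanmean(n, axis=0)
    return float(np.nanmean(diffs))


def call_dmrs(candidates: list[Candidate], matrix: CpGMatrix,
              alpha: float = 0.05, min_cpg: int = 10,
              min_delta: float = 0.10) -> list[DMR]:
    """Test all candidates, adjust jointly with Benjamini-Hochberg, and keep
    those passing all three gates (q < alpha, n_cpg >= min_cpg,
    |delta| >= min_delta)."""
    if not candidates:
        return []
    pvals = np.array([test_candidate(c, matrix) for c in candidates])
    deltas = np.array([_candidate_delta(c, matrix) for c in candidates])
    qvals = bh_adjust(pvals)
    out = []
    for c, p, q, delta in zip(candidates, pvals, qvals, deltas):
        if (q < alpha and c.n_cpg >= min_cpg and abs(delta) >= min_delta):
            out.append(DMR(interval=GenomicInterval(c.chrom, c.start, c.end),
                           n_cpg=c.n_cpg, delta=delta, p_value=float(p),
                           q_value=float(q),
                           direction="hyper" if delta > 0 else "hypo"))
    out.sort(key=lambda d: (d.interval.chrom, d.interval.start))
    return out


def find_dmrs(matrix: CpGMatrix, max_gap_bp: int = 300, min_cpg: int = 10,
              min_delta: float = 0.10, alpha: float = 0.05) -> list[DMR]:
    """Full caller: presegment, segment each window on the mean paired
    difference, test, adjust, gate."""
    chroms = matrix.chroms
    positions = matrix.positions
    delta = matrix.paired_delta()
    candidates: list[Candidate] = []
    for lo, hi in presegment(chroms, positions, max_gap_bp=max_gap_bp,
                             min_cpg=min_cpg):
        candidates.extend(segment(delta[lo:hi], positions[lo:hi],
                                  str(chroms[lo]), min_cpg=min_cpg,
                                  min_delta=min_delta, offset=lo))
    return call_dmrs(candidates, matrix, alpha=alpha, min_cpg=min_cpg,
                     min_delta=min_delta)


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"dmr_id": d.dmr_id, "chrom": d.interval.chrom,
          "start": d.interval.start, "end": d.interval.end,
          "n_cpg": d.n_cpg, "delta": d.delta, "p": d.p_value,
          "q": d.q_value, "direction": d.direction} for d in dmrs],
        columns=["dmr_id", "chrom", "start", "end", "n_cpg", "delta", "p",
                 "q", "direction"])


def summarize(dmrs: list[DMR]) -> pd.DataFrame:
    """Counts, mean length and mean CpG content per direction (zeros on an
    empty call set)."""
    rows = {}
    for direction in ("hyper", "hypo"):
        sub = [d for d in dmrs if d.direction == direction]
        rows[direction] = {
            "n": len(sub),
            "mean_length_bp": float(np.mean([d.interval.length
                                             for d in sub])) if sub else 0.0,
            "mean_n_cpg": float(np.mean([d.n_cpg for d in sub]))
            if sub else 0.0,
            "mean_delta": float(np.mean([d.delta for d in sub]))
            if sub else 0.0}
    return pd.DataFrame(rows).T
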