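"""Statistical primitives shared across stages.

The paired Wilcoxon signed-rank test is exact for small cohorts via a
tie-aware sign-flip distribution; Spearman p-values are exact (full
permutation enumeration) below ten samples.  Multiple testing always uses
Benjamini-Hochberg, the standard FDR-controlling procedure.
"""

from __future__ import annotations

import itertools
import warnings
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["wilcoxon_signed_rank", "spearman", "bh_adjust", "hypergeom_tail",
           "fisher_exact"]


def wilcoxon_signed_rank(diffs, exact_max_n: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for a vector of paired
    differences.

    Zero differences are dropped (Wilcoxon's convention).  With fewer than
    three non-zero differences there is no usable evidence and p = 1 is
    returned with a warning.  For n <= ``exact_max_n`` the exact null
    distribution of W+ is computed by dynamic programming over sign flips
    (average ranks, so ties are handled exactly); beyond that a normal
    approximation with tie-corrected variance and continuity correction is
    used.  The two-sided p is ``min(1, 2 * min(P(W+ <= w), P(W+ >= w)))``.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = d.size
    if n < 3:
        warnings.warn("fewer than 3 non-zero paired differences; p = 1",
                      stacklevel=2)
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # doubled ranks are integers even with average-rank ties
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:counts.size - r]
            counts = counts + shifted
        w2 = int(np.rint(2 * w_plus))
        denom = 2.0 ** n
        p_le = counts[:w2 + 1].sum() / denom
        p_ge = counts[w2:].sum() / denom
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    shift = np.clip(abs(w_plus - mean) - 0.5, 0.0, None)  # continuity
    z = shift / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation and two-sided p-value.

    rho is the Pearson correlation of average ranks (tie-safe).  For
    n <= ``exact_max_n`` the p-value is exact, from full enumeration of rank
    permutations given the observed tie structure; larger n uses the usual
    t approximation.  Degenerate (constant) inputs return ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = _perm_matrix(n)
        ryp = ry[perms]
        rxc = rx - rx.mean()
        ryc = ryp - ryp.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum(axis=1))
        rho_perm = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return rho, p
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (NaN p-values stay NaN and are
    excluded from the family)."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) where X counts
    marked items among K draws from a population of N containing n marked
    items."""
    if not (0 <= k <= K <= N and 0 <= n <= N):
        raise ValueError("inconsistent hypergeometric counts")
    return float(sps.hypergeom.sf(k - 1, N, n, K))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table."""
    return float(sps.fisher_exact(np.asarray(table), alternative="two-sided")[1])
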