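"""QC of the paired CpG methylation matrix: pairing filter, blacklists,
KNN imputation, genome-wide summaries and unsupervised structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .core import CpGMatrix, DEFAULT_SEX_CHROMS, DesignError, validate_design

__all__ = ["FilterReport", "build_matrix", "apply_blacklists", "impute_knn",
           "category_fractions", "top_variable_sites", "cluster_and_project",
           "ClusterProjection"]


@dataclass
class FilterReport:
    """Site counts through the QC funnel; monotone non-increasing."""
    n_input: int = 0
    n_paired_pass: int = 0
    n_heterosome_removed: int = 0
    n_snp_removed: int = 0
    n_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"stage": ["input", "paired-coverage pass",
                                       "heterosome removed", "SNP removed",
                                       "retained"],
                             "sites": [self.n_input, self.n_paired_pass,
                                       self.n_heterosome_removed,
                                       self.n_snp_removed, self.n_retained]})


def build_matrix(columns: dict[str, pd.Series], design: pd.DataFrame,
                 min_paired_patients: int = 10) -> tuple[CpGMatrix, FilterReport]:
    """Merge per-sample rate columns on CpG coordinates and keep sites with a
    non-missing rate in both tissues of at least ``min_paired_patients``
    patients (default 10, the at-least-ten-paired-samples rule)."""
    validate_design(design)
    missing = set(columns) - set(design.index)
    if missing:
        raise DesignError(f"columns without design rows: {sorted(missing)}")
    rates = pd.DataFrame(columns).sort_index()
    rates.index = rates.index.set_names(["chrom", "pos"])
    matrix = CpGMatrix(rates, design.loc[list(rates.columns)])
    t = matrix.rates[matrix.tumor_samples].notna().to_numpy()
    n = matrix.rates[matrix.normal_samples].notna().to_numpy()
    n_paired = (t & n).sum(axis=1)
    keep = n_paired >= min_paired_patients
    report = FilterReport(n_input=matrix.n_sites,
                          n_paired_pass=int(keep.sum()),
                          n_retained=int(keep.sum()))
    return CpGMatrix(matrix.rates[keep], matrix.design), report


def apply_blacklists(matrix: CpGMatrix,
                     sex_chroms=DEFAULT_SEX_CHROMS,
                     snp_intervals: pd.DataFrame | None = None,
                     report: FilterReport | None = None) -> CpGMatrix:
    """Drop CpGs on heterosomes and CpGs whose single-base interval
    intersects any SNP interval.  Removal is pure set subtraction, so the
    two filters commute."""
    chroms = matrix.chroms
    pos = matrix.positions
    keep = ~np.isin(chroms, list(sex_chroms))
    n_het = int((~keep).sum())
    n_snp = 0
    if snp_intervals is not None and len(snp_intervals):
        hit = np.zeros(matrix.n_sites, dtype=bool)
        for chrom, grp in snp_intervals.groupby("chrom"):
            on = chroms == chrom
            if not on.any():
                continue
            p = pos[on]
            local = np.zeros(p.size, dtype=bool)
            for s, e in zip(grp["start"], grp["end"]):
                local |= (p >= s) & (p <= e)
            hit[on] = local
        n_snp = int((hit & keep).sum())
        keep &= ~hit
    if report is not None:
        report.n_heterosome_removed = n_het
        report.n_snp_removed = n_snp
        report.n_retained = int(keep.sum())
    return CpGMatrix(matrix.rates[keep], matrix.design)


def _knn_impute_frame(values: pd.DataFrame, k: int = 10,
                      min_shared: int = 3) -> pd.DataFrame:
    """KNN imputation in feature (row) space: a missing entry is replaced by
    the mean of the k nearest rows' values in that column.  Row distance is
    Euclidean over columns where both rows are observed, scaled to the full
    column count; rows sharing fewer than ``min_shared`` observed columns are
    not neighbors."""
    if k < 1:
        raise ValueError("k must be >= 1")
    X = values.to_numpy(dtype=float)
    n, m = X.shape
    obs = ~np.isnan(X)
    if (~obs).sum() == 0:
        return values
    if (obs.sum(axis=1) == 0).any():
        bad = values.index[obs.sum(axis=1) == 0]
        raise ValueError(f"rows with all values missing cannot be imputed: "
                         f"{list(bad)[:5]}")
    X0 = np.nan_to_num(X, nan=0.0)
    # pairwise shared-column counts and masked squared distances
    shared = obs.astype(float) @ obs.T.astype(float)
    # sum over shared columns of (xi - xj)^2, computed with zero-filled data
    sq = X0 ** 2
    cross = X0 @ X0.T                     # zero-filled, so shared-only
    a_shared = (sq * obs) @ obs.T.astype(float)
    d2 = a_shared + a_shared.T - 2 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(shared >= min_shared, d2 * (m / np.maximum(shared, 1)),
                      np.inf)
    np.fill_diagonal(d2, np.inf)
    out = X.copy()
    for i in np.where(~obs.all(axis=1))[0]:
        order = np.argsort(d2[i], kind="stable")
        order = order[np.isfinite(d2[i][order])]
        for j in np.where(~obs[i])[0]:
            donors = order[obs[order, j]][:k]
            if donors.size == 0:
                raise ValueError(
                    f"no usable neighbor for row {values.index[i]!r}, "
                    f"column {values.columns[j]!r}")
            out[i, j] = X[donors, j].mean()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def impute_knn(matrix: CpGMatrix, k: int = 10,
               min_shared: int = 3) -> CpGMatrix:
    """K-nearest-neighbor imputation in CpG space: each missing rate becomes
    the mean rate of the k nearest CpG sites (Euclidean distance over
    commonly observed samples) in that sample.  Observed values are never
    altered; imputed values stay in [0, 1] (means of rates)."""
    filled = _knn_impute_frame(matrix.rates, k=k, min_shared=min_shared)
    return CpGMatrix(filled, matrix.design)


def category_fractions(matrix: CpGMatrix, low: float = 0.10,
                       high: float = 0.80) -> pd.DataFrame:
    """Per-sample fractions of low (< low), intermediate ([low, high]) and
    high (> high) methylation; both boundaries belong to the intermediate
    class and the three fractions sum to 1."""
    vals = matrix.rates.to_numpy()
    n_obs = (~np.isnan(vals)).sum(axis=0)
    frac_low = np.nansum(vals < low, axis=0) / n_obs
    frac_high = np.nansum(vals > high, axis=0) / n_obs
    return pd.DataFrame({"low": frac_low,
                         "intermediate": 1.0 - frac_low - frac_high,
                         "high": frac_high}, index=matrix.rates.columns)


def top_variable_sites(matrix: CpGMatrix, fraction: float = 0.01) -> CpGMatrix:
    """The top ``ceil(fraction * n)`` sites by variance across all samples."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    var = np.nanvar(matrix.rates.to_numpy(), axis=1)
    n_keep = int(np.ceil(fraction * matrix.n_sites))
    order = np.argsort(-var, kind="stable")[:n_keep]
    keep = np.zeros(matrix.n_sites, dtype=bool)
    keep[order] = True
    return CpGMatrix(matrix.rates[keep], matrix.design)


@dataclass
class ClusterProjection:
    linkage: np.ndarray
    leaf_order: list
    cluster_labels: pd.Series       # two-group cut
    pc_coords: pd.DataFrame         # samples x components, centered
    explained_variance_ratio: np.ndarray
    pearson: pd.DataFrame           # symmetric, unit diagonal


def cluster_and_project(matrix: CpGMatrix,
                        n_components: int = 2) -> ClusterProjection:
    """Ward-linkage hierarchical clustering on Euclidean distances between
    samples, plus a centered principal-component projection and the sample
    Pearson correlation matrix."""
    X = matrix.rates.to_numpy().T  # samples x sites
    if np.isnan(X).any():
        raise ValueError("cluster_and_project needs a complete matrix; "
                         "impute first")
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    if X.var(axis=0).sum() <= 1e-18:
        raise ValueError("constant matrix: PCA is degenerate")
    Z = linkage(pdist(X, metric="euclidean"), method="ward")
    samples = list(matrix.rates.columns)
    labels = fcluster(Z, t=2, criterion="maxclust")
    pca = PCA(n_components=min(n_components, X.shape[0] - 1, X.shape[1]))
    coords = pca.fit_transform(X - X.mean(axis=0, keepdims=True))
    pearson = np.corrcoef(X)
    return ClusterProjection(
        linkage=Z,
        leaf_order=[samples[i] for i in leaves_list(Z)],
        cluster_labels=pd.Series(labels, index=samples),
        pc_coords=pd.DataFrame(
            coords, index=samples,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        pearson=pd.DataFrame(pearson, index=samples, columns=samples))
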