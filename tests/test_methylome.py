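"""QC-stage behavior: pairing filter, blacklists, KNN imputation,
methylation-category fractions, variable-site ranking and clustering."""

import numpy as np
import pandas as pd
import pytest

from methdriver.core import DesignError
from methdriver.methylome import (apply_blacklists, build_matrix,
                                  category_fractions, cluster_and_project,
                                  impute_knn, top_variable_sites)
from tests.conftest import make_design, make_matrix


def columns_from_matrix(values, n_patients, drop=()):
    """Build per-sample rate Series (some entries NaN) for build_matrix."""
    design = make_design(n_patients)
    idx = pd.MultiIndex.from_arrays(
        [["chr1"] * values.shape[0],
         list(np.arange(1, values.shape[0] + 1) * 10)],
        names=["chrom", "pos"])
    cols = {}
    for j, s in enumerate(design.index):
        col = pd.Series(values[:, j], index=idx)
        cols[s] = col
    for site, sample in drop:
        cols[sample].iloc[site] = np.nan
    return cols, design


class TestBuildMatrix:
    def test_paired_coverage_threshold_is_inclusive(self):
        n_pat = 18
        vals = np.full((2, 2 * n_pat), 0.5)
        # site 0: observed in exactly 10 pairs; site 1: 9 pairs
        drop = [(0, f"P{i:02d}T") for i in range(11, 19)]
        drop += [(1, f"P{i:02d}T") for i in range(10, 19)]
        cols, design = columns_from_matrix(vals, n_pat, drop)
        matrix, report = build_matrix(cols, design, min_paired_patients=10)
        assert matrix.n_sites == 1
        assert report.n_input == 2 and report.n_paired_pass == 1

    def test_zero_threshold_keeps_everything(self):
        cols, design = columns_from_matrix(np.full((5, 8), 0.2), 4)
        matrix, report = build_matrix(cols, design, min_paired_patients=0)
        assert matrix.n_sites == 5 == report.n_retained

    def test_unpaired_labels_rejected(self):
        cols, design = columns_from_matrix(np.full((2, 8), 0.2), 4)
        bad_design = design.drop(index="P01N")
        del cols["P01N"]
        with pytest.raises(DesignError):
            build_matrix(cols, bad_design)


class TestBlacklists:
    def _matrix(self):
        design = make_design(2)
        idx = pd.MultiIndex.from_arrays(
            [["chr1", "chr1", "chrX"], [100, 500, 700]],
            names=["chrom", "pos"])
        from methdriver.core import CpGMatrix
        return CpGMatrix(pd.DataFrame(np.full((3, 4), 0.5), index=idx,
                                      columns=design.index), design)

    def test_heterosome_and_exact_snp_overlap_removed(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "start": [500],
                             "end": [500]})
        out = apply_blacklists(self._matrix(), snp_intervals=snps)
        assert list(out.positions) == [100]

    def test_empty_blacklist_is_identity(self):
        m = self._matrix()
        out = apply_blacklists(m, sex_chroms=(), snp_intervals=None)
        pd.testing.assert_frame_equal(out.rates, m.rates)

    def test_filter_order_is_irrelevant(self):
        snps = pd.DataFrame({"chrom": ["chr1", "chrX"], "start": [500, 700],
                             "end": [500, 700]})
        m = self._matrix()
        a = apply_blacklists(apply_blacklists(m, sex_chroms=()),
                             snp_intervals=snps, sex_chroms=("chrX",))
        b = apply_blacklists(apply_blacklists(m, snp_intervals=snps,
                                              sex_chroms=()),
                             sex_chroms=("chrX",))
        pd.testing.assert_frame_equal(a.rates, b.rates)


class TestImputation:
    def test_identical_neighbor_is_copied(self):
        vals = np.array([[0.1, 0.2, 0.7, 0.3],
                         [0.1, 0.2, np.nan, 0.3],
                         [0.9, 0.9, 0.0, 0.9]])
        m = make_matrix(vals, n_patients=2)
        out = impute_knn(m, k=1)
        assert out.rates.iloc[1, 2] == pytest.approx(0.7)

    def test_two_neighbors_average(self):
        vals = np.array([[0.1, 0.2, 0.2, 0.3],
                         [0.1, 0.2, np.nan, 0.3],
                         [0.1, 0.2, 0.6, 0.3]])
        m = make_matrix(vals, n_patients=2)
        out = impute_knn(m, k=2)
        assert out.rates.iloc[1, 2] == pytest.approx(0.4)

    def test_complete_matrix_unchanged(self):
        m = make_matrix(np.random.default_rng(1).uniform(size=(10, 6)))
        out = impute_knn(m, k=3)
        pd.testing.assert_frame_equal(out.rates, m.rates)

    def test_all_missing_site_rejected(self):
        vals = np.full((3, 4), 0.5)
        vals[1] = np.nan
        with pytest.raises(ValueError, match="all values missing"):
            impute_knn(make_matrix(vals, n_patients=2), k=1)

    def test_observed_entries_never_touched_and_bounds_hold(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(size=(40, 12))
        mask = rng.random(vals.shape) < 0.15
        holed = vals.copy()
        holed[mask] = np.nan
        m = make_matrix(holed, n_patients=6)
        out = impute_knn(m, k=5)
        observed = ~np.isnan(holed)
        np.testing.assert_array_equal(out.rates.to_numpy()[observed],
                                      holed[observed])
        assert ((out.rates.to_numpy() >= 0)
                & (out.rates.to_numpy() <= 1)).all()


class TestSummaries:
    def test_category_fractions_partition(self):
        m = make_matrix(np.array([[0.05], [0.5], [0.9]]).repeat(4, axis=1),
                        n_patients=2)
        frac = category_fractions(m)
        np.testing.assert_allclose(frac.iloc[0],
                                   [1 / 3, 1 / 3, 1 / 3])

    def test_boundaries_belong_to_intermediate(self):
        m = make_matrix(np.full((4, 4), 0.10), n_patients=2)
        frac = category_fractions(m)
        np.testing.assert_allclose(frac.iloc[0], [0.0, 1.0, 0.0])
        m = make_matrix(np.full((4, 4), 0.80), n_patients=2)
        np.testing.assert_allclose(category_fractions(m).iloc[0],
                                   [0.0, 1.0, 0.0])

    def test_fractions_sum_to_one(self):
        m = make_matrix(np.random.default_rng(0).uniform(size=(50, 8)))
        np.testing.assert_allclose(category_fractions(m).sum(axis=1), 1.0)

    def test_top_variable_count_and_ranking(self):
        vals = np.full((100, 6), 0.5)
        vals[7] = [0.1, 0.9, 0.1, 0.9, 0.1, 0.9]  # the only variable site
        m = make_matrix(vals, n_patients=3)
        sub = top_variable_sites(m, fraction=0.01)
        assert sub.n_sites == 1
        assert list(sub.positions) == [80]

    def test_fraction_one_keeps_all_sites(self):
        m = make_matrix(np.random.default_rng(1).uniform(size=(30, 6)))
        assert top_variable_sites(m, fraction=1.0).n_sites == 30

    def test_invalid_fraction_rejected(self):
        m = make_matrix(np.random.default_rng(1).uniform(size=(5, 4)))
        with pytest.raises(ValueError):
            top_variable_sites(m, fraction=0.0)


class TestClustering:
    def test_identical_samples_are_perfectly_correlated(self):
        col = np.random.default_rng(3).uniform(size=20)
        vals = np.column_stack([col] * 4) + \
            np.random.default_rng(4).normal(0, 1e-6, size=(20, 4))
        m = make_matrix(vals, n_patients=2)
        proj = cluster_and_project(m)
        assert proj.pearson.iloc[0, 1] > 0.999
        np.testing.assert_allclose(np.diag(proj.pearson), 1.0)
        np.testing.assert_allclose(proj.pearson, proj.pearson.T)

    def test_pc_coordinates_are_centered(self):
        m = make_matrix(np.random.default_rng(5).uniform(size=(60, 10)))
        proj = cluster_and_project(m)
        np.testing.assert_allclose(proj.pc_coords.mean(axis=0), 0.0,
                                   atol=1e-9)

    def test_constant_matrix_is_degenerate(self):
        m = make_matrix(np.full((10, 6), 0.4))
        with pytest.raises(ValueError, match="degenerate|constant"):
            cluster_and_project(m)

    def test_planted_two_group_structure_recovered(self):
        """A 30% tumor shift in 5% of sites separates tissues in the
        two-cluster cut for at least 17 of 18 pairs."""
        rng = np.random.default_rng(42)
        n_sites, n_pat = 2000, 18
        base = rng.uniform(0.1, 0.9, size=n_sites)
        vals = np.clip(base[:, None] + rng.normal(0, 0.05,
                                                  (n_sites, 2 * n_pat)),
                       0, 1)
        shifted = rng.choice(n_sites, size=100, replace=False)
        vals[np.ix_(shifted, np.arange(n_pat))] = np.clip(
            vals[np.ix_(shifted, np.arange(n_pat))] + 0.3, 0, 1)
        m = make_matrix(vals, n_patients=n_pat)
        proj = cluster_and_project(m)
        tissue = m.design["tissue"]
        labels = proj.cluster_labels
        agree = max(
            ((labels == 1) == (tissue == "tumor")).sum(),
            ((labels == 2) == (tissue == "tumor")).sum())
        assert agree >= 2 * n_pat - 1
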