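"""ncRNA analyses: the coding-potential cascade, RPM normalization,
metagene profiles, ncRNA driver calls, host co-regulation and
guilt-by-association."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methdriver.ncrna import (CASCADE_RULES, filter_lncrna,
                              guilt_by_association, host_coregulation,
                              metagene_profile, mirna_normalize,
                              ncrna_drivers)
from tests.conftest import make_matrix


def record(tid, exons=2, length=1000, phylo=10.0, cbl=0.5, orf=40,
           evalue=np.nan):
    return {"transcript_id": tid, "exon_count": exons, "length_bp": length,
            "phylocsf": phylo, "cbl": cbl, "orf_aa": orf,
            "blastx_median_evalue": evalue}


class TestCascade:
    def toy_records(self):
        return pd.DataFrame([
            record("T1", exons=1),                    # rule 1: single exon
            record("T2", length=150),                 # rule 1: short
            record("T3", phylo=60.0),                 # rule 2
            record("T4", cbl=0.5, orf=200),           # rule 3
            record("T5", cbl=0.0, orf=60),            # rule 4
            record("T6", exons=2, length=1000, phylo=10.0, cbl=0.0,
                   orf=40, evalue=1e-10),             # survives everything
        ]).set_index("transcript_id")

    def test_toy_cascade_only_t6_survives(self):
        survivors, removed = filter_lncrna(self.toy_records())
        assert list(survivors.index) == ["T6"]
        assert removed["single_exon_or_short"] == 2
        assert removed["high_phylocsf"] == 1
        assert removed["cbl_positive_long_orf"] == 1
        assert removed["cbl_zero_orf50"] == 1
        assert removed["blastx_hit"] == 0

    def test_removal_counts_balance(self):
        recs = self.toy_records()
        survivors, removed = filter_lncrna(recs)
        assert sum(removed.values()) == len(recs) - len(survivors)

    def test_empty_input(self):
        survivors, removed = filter_lncrna(
            self.toy_records().iloc[:0])
        assert len(survivors) == 0
        assert all(v == 0 for v in removed.values())

    def test_phylocsf_boundary_is_strict(self):
        recs = pd.DataFrame([record("T", phylo=50.0)]) \
            .set_index("transcript_id")
        survivors, _ = filter_lncrna(recs)
        assert len(survivors) == 1   # "greater than 50" keeps exactly 50

    def test_missing_blastx_means_keep(self):
        recs = pd.DataFrame([record("T", evalue=np.nan)]) \
            .set_index("transcript_id")
        survivors, _ = filter_lncrna(recs)
        assert len(survivors) == 1

    def test_rule_order_does_not_change_survivors(self):
        rng = np.random.default_rng(8)
        recs = pd.DataFrame([
            record(f"T{i}", exons=int(rng.integers(1, 4)),
                   length=int(rng.integers(100, 3000)),
                   phylo=float(rng.normal(30, 30)),
                   cbl=float(rng.choice([0.0, 0.4, 1.2])),
                   orf=int(rng.integers(0, 250)),
                   evalue=float(rng.choice([np.nan, 1e-30, 1e-5])))
            for i in range(60)]).set_index("transcript_id")
        baseline, _ = filter_lncrna(recs)
        from methdriver.ncrna import _rule_masks
        masks = _rule_masks(recs)
        for perm in itertools.permutations(CASCADE_RULES[1:]):
            remaining = recs[~masks[CASCADE_RULES[0]]]
            for rule in perm:
                remaining = remaining[~masks[rule].loc[remaining.index]]
            assert list(remaining.index) == list(baseline.index)


class TestMirnaNormalize:
    def test_rpm_arithmetic(self):
        counts = pd.DataFrame({"s1": [5, 0, 10 ** 6]},
                              index=["m1", "m2", "m3"])
        sizes = pd.Series({"s1": 10 ** 6})
        out = mirna_normalize(counts, sizes)
        assert out.loc["m1", "s1"] == pytest.approx(np.log2(6), abs=1e-3)
        assert out.loc["m2", "s1"] == 0.0
        assert out.loc["m3", "s1"] == pytest.approx(np.log2(10 ** 6 + 1),
                                                    abs=1e-3)

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"s1": [5]})
        with pytest.raises(ValueError):
            mirna_normalize(counts, pd.Series({"s1": 0}))


class TestMetagene:
    def _genes(self, start=20_000, end=30_000, strand="+"):
        return pd.DataFrame({"gene_id": ["G1"], "chrom": ["chr1"],
                             "start": [start], "end": [end],
                             "strand": [strand], "biotype": ["coding"],
                             "host_gene": [pd.NA]})

    def test_constant_field_gives_constant_profile(self):
        pos = np.arange(10_000, 40_000, 200)
        m = make_matrix(np.full((pos.size, 8), 0.5), positions=pos)
        prof = metagene_profile(m, self._genes())
        vals = prof.bins[["tumor", "normal"]].to_numpy()
        np.testing.assert_allclose(vals[~np.isnan(vals)], 0.5)

    def test_bin_count_formula(self):
        pos = np.arange(10_000, 40_000, 200)
        m = make_matrix(np.full((pos.size, 8), 0.5), positions=pos)
        prof = metagene_profile(m, self._genes())
        assert len(prof.bins) == 41 + 40 + 41
        assert (prof.bins["region"] == "upstream").sum() == 41

    def test_step_function_separates_flank_and_body(self):
        pos = np.arange(10_000, 40_001, 100)
        vals = np.where((pos >= 20_000) & (pos <= 30_000), 1.0, 0.0)
        m = make_matrix(np.tile(vals[:, None], (1, 8)), positions=pos)
        prof = metagene_profile(m, self._genes())
        body = prof.bins[prof.bins["region"] == "body"]["tumor"]
        up = prof.bins[prof.bins["region"] == "upstream"]["tumor"]
        assert body.mean() > 0.99
        assert up.iloc[:30].max() < 0.01  # distal windows untouched

    def test_minus_strand_profile_is_flipped(self):
        pos = np.arange(10_000, 40_001, 100)
        vals = np.where(pos < 20_000, 1.0, 0.0)  # high left of the gene
        m = make_matrix(np.tile(vals[:, None], (1, 8)), positions=pos)
        plus = metagene_profile(m, self._genes(strand="+"))
        minus = metagene_profile(m, self._genes(strand="-"))
        # left-of-gene methylation is upstream for '+', downstream for '-'
        assert plus.bins[plus.bins["region"] == "upstream"]["tumor"] \
            .iloc[0] == pytest.approx(1.0)
        assert minus.bins[minus.bins["region"] == "downstream"]["tumor"] \
            .iloc[-1] == pytest.approx(1.0)

    def test_planted_tss_dip_localized(self):
        pos = np.arange(10_000, 40_001, 100)
        dip = np.exp(-((pos - 20_000) / 600.0) ** 2)
        vals = 0.8 - 0.7 * dip
        m = make_matrix(np.tile(vals[:, None], (1, 8)), positions=pos)
        prof = metagene_profile(m, self._genes())
        tumor = prof.bins["tumor"].to_numpy()
        tss_bin = 41  # first body bin sits at the TSS
        assert abs(int(np.nanargmin(tumor)) - tss_bin) <= 2

    def test_short_gene_excluded_and_reported(self):
        pos = np.arange(10_000, 40_000, 200)
        m = make_matrix(np.full((pos.size, 8), 0.5), positions=pos)
        genes = self._genes(start=20_000, end=20_500)
        prof = metagene_profile(m, genes)
        assert prof.n_genes_used == 0 and prof.n_genes_excluded == 1


class TestNcrnaDrivers:
    def test_planted_ncrna_drivers_recovered(self, dataset, called_dmrs):
        genes = dataset.annotation.genes
        nc = genes[genes["biotype"].isin(["lncRNA", "miRNA"])]
        calls = ncrna_drivers(called_dmrs, nc, dataset.matrix,
                              dataset.expression)
        truth = dataset.truth.drivers
        planted = set(truth.loc[truth["biotype"] != "coding", "gene_id"])
        got = set(calls["gene_id"])
        assert len(got & planted) >= 0.8 * len(planted)
        assert set(calls["biotype"]) <= {"lncRNA", "miRNA"}

    def test_host_coregulation_requires_shared_dmr(self, dataset,
                                                   called_dmrs, funnel):
        genes = dataset.annotation.genes
        nc = genes[genes["biotype"].isin(["lncRNA", "miRNA"])]
        nc_calls = ncrna_drivers(called_dmrs, nc, dataset.matrix,
                                 dataset.expression)
        pairs = host_coregulation(nc_calls, funnel["discovery"], nc)
        truth = dataset.truth.drivers
        nested = truth[truth["host_gene"].notna()]
        # every planted nested driver pair shares its host's promoter DMR
        assert set(pairs["ncrna_id"]) == set(nested["gene_id"])
        for _, r in pairs.iterrows():
            assert r["host_gene"] in set(funnel["discovery"]["gene_id"])

    def test_non_driver_host_is_not_reported(self):
        nc_calls = pd.DataFrame([{"gene_id": "M1", "dmr_id": "d1",
                                  "direction": "hyper-driver"}])
        gene_calls = pd.DataFrame([{"gene_id": "G_OTHER", "dmr_id": "d1"}])
        models = pd.DataFrame({"gene_id": ["M1"], "host_gene": ["G_HOST"]})
        assert len(host_coregulation(nc_calls, gene_calls, models)) == 0

    def test_distinct_dmrs_are_not_coregulated(self):
        nc_calls = pd.DataFrame([{"gene_id": "M1", "dmr_id": "d1",
                                  "direction": "hyper-driver"}])
        gene_calls = pd.DataFrame([{"gene_id": "G_HOST", "dmr_id": "d2"}])
        models = pd.DataFrame({"gene_id": ["M1"], "host_gene": ["G_HOST"]})
        assert len(host_coregulation(nc_calls, gene_calls, models)) == 0


class TestGuiltByAssociation:
    def test_near_copy_is_coexpressed(self):
        rng = np.random.default_rng(1)
        target = pd.Series(rng.uniform(1, 100, 36),
                           index=[f"s{i}" for i in range(36)])
        coding = pd.DataFrame(
            {"gene_id": ["near", "indep"],
             **{s: [target[s] + rng.normal(0, 0.01),
                    rng.uniform(1, 100)] for s in target.index}}
        ).set_index("gene_id")
        out = guilt_by_association(target, coding).set_index("gene_id")
        assert out.loc["near", "coexpressed"]
        assert out.loc["near", "rho"] > 0.99
        assert not out.loc["indep", "coexpressed"]

    def test_boundary_rho_is_strict(self):
        out = pd.DataFrame({"gene_id": ["g"], "rho": [0.5], "p": [1e-9]})
        # rho exactly at the threshold is excluded by the strict inequality
        from methdriver.stats import bh_adjust
        assert not ((np.abs(out["rho"]) > 0.5) & (bh_adjust(out["p"])
                                                  < 0.01)).iloc[0]

    def test_too_few_samples_rejected(self):
        target = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        coding = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]},
                              index=["g"])
        with pytest.raises(ValueError):
            guilt_by_association(target, coding)
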