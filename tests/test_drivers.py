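"""Driver funnel: differential expression, pairing/correlation, best-pair
selection, discovery gates, probe validation and tiering."""

import numpy as np
import pandas as pd
import pytest

from methdriver import drivers as drv
from methdriver.core import ExpressionMatrix
from tests.conftest import make_design


def expr_matrix(values, n_patients):
    design = make_design(n_patients)
    return ExpressionMatrix(pd.DataFrame(
        values, index=[f"G{i}" for i in range(len(values))],
        columns=design.index), design)


class TestDifferentialExpression:
    def test_fold_change_arithmetic(self):
        n = 6
        vals = np.vstack([np.array([8.0] * n + [2.0] * n)
                          + np.random.default_rng(0).normal(0, 0.1, 2 * n)])
        de = drv.differential_expression(expr_matrix(vals, n))
        assert de.loc["G0", "fc"] == pytest.approx(4.0, rel=0.05)
        assert de.loc["G0", "log2fc"] == pytest.approx(2.0, abs=0.1)

    def test_identical_groups_carry_no_evidence(self):
        vals = np.array([[5.0] * 12])
        de = drv.differential_expression(expr_matrix(vals, 6))
        assert de.loc["G0", "p"] == 1.0

    def test_low_expression_filter(self):
        vals = np.array([[0.5] * 12, [5.0] * 6 + [1.0] * 6])
        de = drv.differential_expression(expr_matrix(vals, 6),
                                         min_q90_rpkm=1.0)
        assert "G0" not in de.index and "G1" in de.index

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 patient pairs"):
            drv.differential_expression(expr_matrix(np.ones((1, 4)), 2))


class TestPairing:
    def _setup(self):
        """One gene, one DMR fully inside its promoter, 4 patients."""
        from tests.conftest import make_matrix
        n_pat = 4
        meth_levels = np.array([0.1, 0.3, 0.5, 0.7, 0.2, 0.4, 0.6, 0.8])
        vals = np.tile(meth_levels, (12, 1))
        matrix = make_matrix(vals, positions=np.arange(12) * 20 + 9000,
                             n_patients=n_pat)
        genes = pd.DataFrame({"gene_id": ["G0"], "chrom": ["chr1"],
                              "start": [9100], "end": [20_000],
                              "strand": ["+"], "biotype": ["coding"],
                              "host_gene": [pd.NA]})
        expr_vals = (2.0 ** (8 - 8 * meth_levels))[None, :]
        expr = expr_matrix(expr_vals, n_pat)
        dmrs = pd.DataFrame({"dmr_id": ["chr1:9000-9220"],
                             "chrom": ["chr1"], "start": [9000],
                             "end": [9220], "delta": [0.3]})
        return dmrs, genes, matrix, expr

    def test_monotone_coupling_gives_perfect_negative_rho(self):
        dmrs, genes, matrix, expr = self._setup()
        pairs = drv.pair_and_correlate(dmrs, genes, matrix, expr)
        assert len(pairs) == 1
        assert pairs.loc[0, "rho"] == pytest.approx(-1.0)

    def test_constant_methylation_drops_pair_with_warning(self):
        dmrs, genes, matrix, expr = self._setup()
        flat = matrix.rates.copy()
        flat.iloc[:, :] = 0.5
        from methdriver.core import CpGMatrix
        matrix2 = CpGMatrix(flat, matrix.design)
        with pytest.warns(UserWarning, match="degenerate"):
            pairs = drv.pair_and_correlate(dmrs, genes, matrix2, expr)
        assert len(pairs) == 0

    def test_gene_without_expression_is_skipped(self):
        dmrs, genes, matrix, expr = self._setup()
        expr2 = ExpressionMatrix(expr.values.rename(index={"G0": "ZZ"}),
                                 expr.design)
        pairs = drv.pair_and_correlate(dmrs, genes, matrix, expr2)
        assert len(pairs) == 0


class TestBestPair:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "dmr_id", "chrom",
                                           "start", "end", "delta", "rho",
                                           "p", "q"])

    def test_most_negative_rho_wins(self):
        pairs = self._pairs([("G1", "a", "chr1", 1, 10, 0.3, -0.2, 0.1, 0.1),
                             ("G1", "b", "chr1", 50, 60, 0.3, -0.5, 0.1,
                              0.1)])
        best = drv.select_best_per_gene(pairs)
        assert list(best["dmr_id"]) == ["b"]

    def test_tie_broken_by_smaller_p_then_position(self):
        pairs = self._pairs([("G1", "a", "chr1", 9, 10, 0.3, -0.4, 0.03,
                              0.1),
                             ("G1", "b", "chr1", 1, 5, 0.3, -0.4, 0.01,
                              0.1)])
        assert list(drv.select_best_per_gene(pairs)["dmr_id"]) == ["b"]
        pairs = self._pairs([("G1", "a", "chr1", 9, 10, 0.3, -0.4, 0.01,
                              0.1),
                             ("G1", "b", "chr1", 1, 5, 0.3, -0.4, 0.01,
                              0.1)])
        assert list(drv.select_best_per_gene(pairs)["dmr_id"]) == ["b"]

    def test_single_pair_is_returned(self):
        pairs = self._pairs([("G1", "a", "chr1", 1, 10, 0.3, -0.2, 0.1,
                              0.1)])
        assert len(drv.select_best_per_gene(pairs)) == 1


class TestDiscoveryGates:
    def _best(self, rho, q_pair=0.01):
        return pd.DataFrame([{"gene_id": "G1", "dmr_id": "d", "chrom":
                              "chr1", "start": 1, "end": 10, "delta": 0.4,
                              "rho": rho, "p": q_pair, "q": q_pair}])

    def _de(self, fc=3.0, q=0.01):
        return pd.DataFrame({"mean_tumor": [fc], "mean_normal": [1.0],
                             "fc": [fc], "log2fc": [np.log2(fc)],
                             "p": [q], "q": [q]},
                            index=pd.Index(["G1"], name="gene_id"))

    def test_rho_gate_is_strict_at_threshold(self):
        de = self._de(fc=0.25)  # downregulated, matches hyper delta
        assert len(drv.discovery_list(self._best(-0.31), de)) == 1
        assert len(drv.discovery_list(self._best(-0.29), de)) == 0

    def test_fold_change_gate_is_two_sided(self):
        assert len(drv.discovery_list(self._best(-0.5), self._de(fc=0.4))) \
            == 1
        assert len(drv.discovery_list(self._best(-0.5), self._de(fc=1.5))) \
            == 0

    def test_direction_assignment(self):
        out = drv.discovery_list(self._best(-0.5), self._de(fc=0.25))
        assert out.loc[0, "direction"] == "hyper-driver"

    def test_planted_drivers_recovered(self, dataset, funnel):
        disc = funnel["discovery"]
        truth = dataset.truth.drivers
        planted = set(truth.loc[truth["biotype"] == "coding", "gene_id"])
        got = set(disc["gene_id"])
        assert len(got & planted) >= 0.9 * len(planted)
        assert len(got - planted) <= 0.05 * max(len(got), 1)


class TestValidation:
    def test_best_probe_and_untestable_handling(self, dataset, funnel):
        val = funnel["validations"]["cohortA"]
        assert val["testable"].any()
        # planted drivers validate almost surely at n=80 with strong slope
        truth = dataset.truth.drivers
        planted = set(truth.loc[truth["biotype"] == "coding", "gene_id"])
        sub = val[val["gene_id"].isin(planted)]
        assert sub["validated"].mean() >= 0.9

    def test_gene_without_promoter_probe_is_untestable(self, dataset,
                                                       funnel):
        cohort = dataset.cohorts["cohortA"]
        coding = funnel["coding"]
        out = drv.validate_on_probes(["NOT_A_GENE"], cohort.betas,
                                     cohort.probe_positions, cohort.expr,
                                     coding)
        assert not out.loc[0, "testable"]
        assert not out.loc[0, "validated"]


class TestTiering:
    def _discovery_row(self, gene):
        return {"gene_id": gene, "dmr_id": "d", "rho": -0.5,
                "q_pair": 0.01, "fc": 0.3, "q_de": 0.01,
                "direction": "hyper-driver", "delta": 0.4,
                "log2fc": -1.7}

    def _validation(self, genes, validated):
        return pd.DataFrame({"gene_id": genes, "testable": True,
                             "rho": -0.6, "p": 1e-4, "q": 1e-3,
                             "validated": validated})

    def test_both_cohorts_high_one_moderate(self):
        disc = pd.DataFrame([self._discovery_row("G1"),
                             self._discovery_row("G2")])
        vals = {"A": self._validation(["G1", "G2"], [True, True]),
                "B": self._validation(["G1", "G2"], [True, False])}
        tiers = drv.tier_and_classify(disc, vals)
        assert tiers.set_index("gene_id").loc["G1", "tier"] == "high"
        assert tiers.set_index("gene_id").loc["G2", "tier"] == "moderate"

    def test_funnel_is_monotone(self, funnel):
        tiers = funnel["tiers"]
        primary = set(funnel["discovery"]["gene_id"])
        high = set(tiers.loc[tiers["tier"] == "high", "gene_id"])
        mod_or_high = set(tiers.loc[tiers["tier"].isin(["high", "moderate"]),
                                    "gene_id"])
        assert high <= mod_or_high <= primary

    def test_planted_direction_split_reproduced(self, dataset, funnel):
        tiers = funnel["tiers"]
        high = tiers[tiers["tier"] == "high"]
        n_hyper = int((high["direction"] == "hyper-driver").sum())
        n_hypo = int((high["direction"] == "hypo-driver").sum())
        cfg = dataset.config
        assert abs(n_hyper - cfg.n_hyper_drivers) <= 2
        assert abs(n_hypo - cfg.n_hypo_drivers) <= 2

    def test_every_call_carries_its_evidence(self, funnel):
        tiers = funnel["tiers"]
        for col in ("rho", "q_pair", "fc", "q_de", "dmr_id"):
            assert col in tiers.columns
            assert tiers[col].notna().all()
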