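"""Shared fixtures: one session-scoped simulated study reused by the
pipeline-level tests, plus helpers to build tiny matrices by hand."""

import numpy as np
import pandas as pd
import pytest

from methdriver import dmr as dmrmod
from methdriver import drivers as drv
from methdriver.core import NORMAL, TUMOR, CpGMatrix, ExpressionMatrix
from methdriver.simulate import SimulationConfig, simulate_dataset


def make_design(n_patients: int) -> pd.DataFrame:
    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    return pd.DataFrame(
        {"patient": patients * 2,
         "tissue": [TUMOR] * n_patients + [NORMAL] * n_patients},
        index=[f"{p}T" for p in patients] + [f"{p}N" for p in patients])


def make_matrix(values, positions=None, chrom="chr1",
                n_patients=None) -> CpGMatrix:
    """CpGMatrix from a (sites x samples) array; first half of the columns
    are tumors, second half matched normals."""
    values = np.asarray(values, dtype=float)
    if n_patients is None:
        n_patients = values.shape[1] // 2
    design = make_design(n_patients)
    if positions is None:
        positions = np.arange(1, values.shape[0] + 1) * 10
    idx = pd.MultiIndex.from_arrays(
        [[chrom] * values.shape[0], list(positions)], names=["chrom", "pos"])
    return CpGMatrix(pd.DataFrame(values, index=idx, columns=design.index),
                     design)


@pytest.fixture(scope="session")
def dataset():
    """Default-condition simulated study (18 pairs, planted DMRs and
    drivers, two validation cohorts)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def called_dmrs(dataset):
    return dmrmod.find_dmrs(dataset.matrix)


@pytest.fixture(scope="session")
def funnel(dataset, called_dmrs):
    """Discovery + two-cohort validation funnel on the session dataset."""
    genes = dataset.annotation.genes
    coding = genes[genes["biotype"] == "coding"]
    de = drv.differential_expression(dataset.expression)
    pairs = drv.pair_and_correlate(called_dmrs, coding, dataset.matrix,
                                   dataset.expression)
    best = drv.select_best_per_gene(pairs)
    disc = drv.discovery_list(best, de)
    vals = {name: drv.validate_on_probes(disc["gene_id"], c.betas,
                                         c.probe_positions, c.expr, coding)
            for name, c in dataset.cohorts.items()}
    tiers = drv.tier_and_classify(disc, vals)
    return {"coding": coding, "de": de, "pairs": pairs, "best": best,
            "discovery": disc, "validations": vals, "tiers": tiers}
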