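"""Synthetic paired tumor/normal methylome-transcriptome datasets with
planted ground truth.

The generator emulates the design of an RRBS study of matched tumor and
adjacent-normal tissue pairs: CpGs occur in clusters (promoter CGI-like
clusters with low baseline methylation, background clusters with high
baseline), per-site coverage is negative-binomially overdispersed,
methylated counts are binomial, and differential regions are planted as
contiguous CpG blocks whose tumor methylation is shifted by +/-delta.
Planted driver genes couple their expression to promoter methylation with a
negative log-linear slope; probe-level beta matrices for independent
validation cohorts mirror the promoter methylation with array-like noise.

Everything is deterministic under the single config seed; per-stage
substreams are spawned from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import NORMAL, TUMOR, CpGMatrix, ExpressionMatrix

__all__ = ["SimulationConfig", "Annotation", "GroundTruth", "Methylome",
           "ProbeCohort", "SimulatedDataset", "simulate_annotation",
           "simulate_methylome", "simulate_expression",
           "simulate_probe_cohort", "simulate_dataset"]


class ConfigError(ValueError):
    """Simulation parameters are infeasible (e.g. genes exceed chromosome)."""


@dataclass
class SimulationConfig:
    """Study-design knobs for the simulator.  Defaults mirror the paired
    18-patient design at a desk-scale genome (two chromosomes of 4 Mb)."""

    seed: int = 0
    n_patients: int = 18

    # genome geometry
    n_chromosomes: int = 2
    chrom_length: int = 4_000_000

    # gene complement
    n_coding: int = 60
    n_lncrna: int = 12
    n_mirna: int = 8
    n_host_pairs: int = 3          # driver ncRNAs nested in driver hosts
    coding_length: tuple = (8_000, 30_000)
    lncrna_length: tuple = (1_000, 8_000)
    mirna_length: tuple = (500, 2_000)
    poised_fraction: float = 0.6   # ESC-poised coding promoters
    active_fraction: float = 0.3

    # CpG clusters
    promoter_cpgs: int = 30
    promoter_spacing: float = 15.0
    n_background_clusters: int = 120
    cluster_cpgs: tuple = (15, 50)
    background_spacing: float = 25.0

    # methylation model
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    coverage_const: int | None = None   # force constant coverage (tests)
    cgi_beta: tuple = (0.5, 10.0)
    background_beta: tuple = (10.0, 0.5)
    sample_noise_sd: float = 0.05

    # planted generic DMRs
    n_dmrs: int = 50
    dmr_width_cpg: int = 15
    dmr_delta: float = 0.4
    dmr_hyper_fraction: float = 0.5
    hyper_placement: dict = field(default_factory=lambda: {
        "poised-promoter": 0.46, "active-promoter": 0.11, "intergenic": 0.43})
    hypo_placement: dict = field(default_factory=lambda: {
        "poised-promoter": 0.10, "active-promoter": 0.10, "intergenic": 0.80})

    # planted drivers
    n_hyper_drivers: int = 20
    n_hypo_drivers: int = 11
    n_lncrna_drivers: int = 8
    n_mirna_drivers: int = 5
    driver_delta: float = 0.4
    coupling_slope: float = 4.0
    expr_noise_sd: float = 0.5
    expr_baseline_log2: tuple = (2.0, 6.0)

    # chromatin-state epigenomes
    n_esc: int = 3
    n_tissue: int = 2
    state_flip_prob: float = 0.1

    # TF motifs
    n_tf_groups: int = 20
    planted_tf: str | None = "TF01"
    planted_tf_interest_fraction: float = 0.6
    background_motif_fraction: float = 0.05

    # SNP blacklist
    n_snps: int = 200

    # validation cohorts (array-style probes)
    validation_cohorts: tuple = ("cohortA", "cohortB")
    validation_n_tumor: int = 40
    validation_n_normal: int = 40
    probes_per_promoter: int = 2
    probe_noise_sd: float = 0.05
    probe_missing_rate: float = 0.02


@dataclass
class GroundTruth:
    """Planted-truth ledger: every planted element maps to a generated
    annotation entity."""
    dmrs: pd.DataFrame        # dmr_id, chrom, start, end, n_cpg, delta, ...
    drivers: pd.DataFrame     # gene_id, biotype, direction, host_gene
    planted_tf: str | None


@dataclass
class Annotation:
    chrom_sizes: dict
    genes: pd.DataFrame       # GTF-lite columns + promoter_class
    cpgs: pd.DataFrame        # chrom, pos, cluster_id, kind, gene_id
    cgis: pd.DataFrame        # chrom, start, end
    states: dict              # epigenome id -> state segmentation frame
    esc_ids: list
    tissue_ids: list
    motifs: pd.DataFrame      # tf, chrom, start, end
    snps: pd.DataFrame        # chrom, start, end (single-base)


@dataclass
class Methylome:
    """Per-sample CpG counts over the annotation's site list."""
    cpgs: pd.DataFrame
    meth: np.ndarray          # sites x samples methylated counts
    cov: np.ndarray           # sites x samples total counts
    design: pd.DataFrame

    @property
    def samples(self) -> list:
        return list(self.design.index)

    def sample_counts(self, sample: str) -> pd.DataFrame:
        j = self.samples.index(sample)
        return pd.DataFrame({"chrom": self.cpgs["chrom"],
                             "pos": self.cpgs["pos"],
                             "C": self.meth[:, j], "N": self.cov[:, j]})

    def to_matrix(self, coverage_min: int = 5) -> CpGMatrix:
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = self.meth / self.cov
        rates = np.where(self.cov >= coverage_min, rates, np.nan)
        idx = pd.MultiIndex.from_frame(self.cpgs[["chrom", "pos"]])
        return CpGMatrix(pd.DataFrame(rates, index=idx, columns=self.samples),
                         self.design)


@dataclass
class ProbeCohort:
    """Array-style validation cohort: probe betas plus expression for an
    independent (unpaired) set of tumor and normal samples."""
    name: str
    betas: pd.DataFrame       # probes x samples, NaN = missing
    probe_positions: pd.DataFrame  # probe_id, chrom, pos
    expr: pd.DataFrame        # genes x samples, linear RPKM
    labels: pd.Series         # sample -> tumor/normal


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: Annotation
    truth: GroundTruth
    methylome: Methylome
    matrix: CpGMatrix
    expression: ExpressionMatrix
    cohorts: dict


# ---------------------------------------------------------------------------
# annotation + planted truth
# ---------------------------------------------------------------------------

def _alloc(n: int, k: int) -> list:
    """Split n items into k nearly equal groups."""
    base = n // k
    sizes = [base + (1 if i < n % k else 0) for i in range(k)]
    return sizes


def _class_counts(n: int, fractions: dict) -> dict:
    keys = list(fractions)
    counts = {k: int(np.floor(fractions[k] * n)) for k in keys}
    short = n - sum(counts.values())
    order = sorted(keys, key=lambda k: -(fractions[k] * n - counts[k]))
    for k in order[:short]:
        counts[k] += 1
    return counts


def simulate_annotation(config: SimulationConfig) -> tuple[Annotation, GroundTruth]:
    ss = np.random.SeedSequence(config.seed)
    (s_layout, s_cpg, s_classes, s_states, s_motifs, s_snps) = ss.spawn(6)
    rng = np.random.default_rng(s_layout)

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_sizes = {c: config.chrom_length for c in chroms}

    # ---- place standalone genes ------------------------------------------
    specs = ([("G", "coding", config.coding_length)] * config.n_coding
             + [("L", "lncRNA", config.lncrna_length)]
             * (config.n_lncrna - min(config.n_host_pairs, 1))
             + [("M", "miRNA", config.mirna_length)]
             * (config.n_mirna - max(config.n_host_pairs - 1, 0)))
    n_per_chrom = _alloc(len(specs), len(chroms))
    rows, counters = [], {"G": 0, "L": 0, "M": 0}
    zone_end = {}
    it = iter(specs)
    for chrom, n_here in zip(chroms, n_per_chrom):
        cursor = 100_000
        for _ in range(n_here):
            prefix, biotype, lrange = next(it)
            counters[prefix] += 1
            length = int(rng.integers(lrange[0], lrange[1] + 1))
            start = cursor + int(rng.integers(6_000, 14_000))
            end = start + length - 1
            if end > config.chrom_length * 0.5:
                raise ConfigError(
                    f"gene layout exceeds half of {chrom}; shrink the gene "
                    "complement or grow chrom_length")
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append([f"{prefix}{counters[prefix]:04d}", chrom, start, end,
                         strand, biotype, pd.NA])
            cursor = end
        zone_end[chrom] = cursor
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand", "biotype", "host_gene"])

    # ---- promoter classes and driver assignment --------------------------
    rng_cls = np.random.default_rng(s_classes)
    coding = genes.index[genes["biotype"] == "coding"].to_numpy()
    perm = rng_cls.permutation(coding)
    n_poised = int(round(config.poised_fraction * len(coding)))
    n_active = int(round(config.active_fraction * len(coding)))
    promoter_class = pd.Series("other", index=genes.index)
    promoter_class.iloc[perm[:n_poised]] = "poised"
    promoter_class.iloc[perm[n_poised:n_poised + n_active]] = "active"
    promoter_class[genes["biotype"] != "coding"] = "other"
    genes["promoter_class"] = promoter_class

    poised_pool = list(genes.loc[(genes["promoter_class"] == "poised"),
                                 "gene_id"])
    active_pool = list(genes.loc[(genes["promoter_class"] == "active"),
                                 "gene_id"])
    other_pool = list(genes.loc[(genes["biotype"] == "coding")
                                & (genes["promoter_class"] == "other"),
                                "gene_id"])
    rng_cls.shuffle(poised_pool)
    rng_cls.shuffle(active_pool)
    rng_cls.shuffle(other_pool)

    if config.n_hyper_drivers + config.n_hypo_drivers > len(coding):
        raise ConfigError("more planted coding drivers than coding genes")
    n_hyper_poised = min(int(round(0.8 * config.n_hyper_drivers)),
                         len(poised_pool))
    hyper_drivers = [poised_pool.pop() for _ in range(n_hyper_poised)]
    while len(hyper_drivers) < config.n_hyper_drivers:
        hyper_drivers.append((active_pool or poised_pool or other_pool).pop())
    hypo_drivers = []
    while len(hypo_drivers) < config.n_hypo_drivers:
        hypo_drivers.append((other_pool or active_pool or poised_pool).pop())

    lnc_ids = list(genes.loc[genes["biotype"] == "lncRNA", "gene_id"])
    mir_ids = list(genes.loc[genes["biotype"] == "miRNA", "gene_id"])

    driver_rows = [(g, "coding", "hyper", pd.NA) for g in hyper_drivers]
    driver_rows += [(g, "coding", "hypo", pd.NA) for g in hypo_drivers]

    # ---- nested (host-pair) ncRNA drivers --------------------------------
    host_rows = []
    n_pairs = min(config.n_host_pairs, len(hyper_drivers))
    for i in range(n_pairs):
        host = genes.loc[genes["gene_id"] == hyper_drivers[i]].iloc[0]
        prefix = "M" if i % 2 == 0 else "L"
        counters[prefix] += 1
        nc_id = f"{prefix}{counters[prefix]:04d}"
        biotype = "miRNA" if prefix == "M" else "lncRNA"
        if host["strand"] == "+":
            nc_start = host["start"] + 400
            nc_end = min(nc_start + 900, host["end"])
            nc_tss_strand = "+"
        else:
            nc_end = host["end"] - 400
            nc_start = max(nc_end - 900, host["start"])
            nc_tss_strand = "-"
        host_rows.append([nc_id, host["chrom"], nc_start, nc_end,
                          nc_tss_strand, biotype, host["gene_id"], "other"])
        driver_rows.append((nc_id, biotype, "hyper", host["gene_id"]))
        if biotype == "miRNA":
            mir_ids.append(nc_id)
        else:
            lnc_ids.append(nc_id)
    if host_rows:
        genes = pd.concat([genes, pd.DataFrame(host_rows,
                                               columns=list(genes.columns))],
                          ignore_index=True)

    # standalone ncRNA drivers (hyper direction; promoters get their own DMR)
    n_nested_mi = sum(1 for r in host_rows if r[5] == "miRNA")
    n_nested_ln = sum(1 for r in host_rows if r[5] == "lncRNA")
    free_lnc = [g for g in lnc_ids
                if g not in {r[0] for r in driver_rows}]
    free_mir = [g for g in mir_ids
                if g not in {r[0] for r in driver_rows}]
    for g in free_lnc[:max(config.n_lncrna_drivers - n_nested_ln, 0)]:
        driver_rows.append((g, "lncRNA", "hyper", pd.NA))
    for g in free_mir[:max(config.n_mirna_drivers - n_nested_mi, 0)]:
        driver_rows.append((g, "miRNA", "hyper", pd.NA))
    drivers = pd.DataFrame(driver_rows,
                           columns=["gene_id", "biotype", "direction",
                                    "host_gene"])

    # ---- CpG clusters -----------------------------------------------------
    rng_cpg = np.random.default_rng(s_cpg)
    cpg_rows = []  # chrom, pos, cluster_id, kind, gene_id
    cluster_id = 0
    promoter_cluster = {}
    nested = {r[0] for r in host_rows}
    for _, g in genes.iterrows():
        if g["gene_id"] in nested:
            continue  # nested ncRNAs share the host promoter cluster
        tss = g["start"] if g["strand"] == "+" else g["end"]
        span = config.promoter_cpgs * config.promoter_spacing
        pos = int(tss - span / 2)
        gaps = 2 + rng_cpg.geometric(1.0 / config.promoter_spacing,
                                     size=config.promoter_cpgs)
        positions = pos + np.concatenate([[0], np.cumsum(gaps[:-1])])
        for p in positions:
            cpg_rows.append([g["chrom"], int(p), cluster_id, "promoter",
                             g["gene_id"]])
        promoter_cluster[g["gene_id"]] = cluster_id
        cluster_id += 1

    n_bg_per_chrom = _alloc(config.n_background_clusters, len(chroms))
    background_clusters = []
    for chrom, n_here in zip(chroms, n_bg_per_chrom):
        zone_lo = max(z for c, z in zone_end.items() if c == chrom) + 10_000
        zone_hi = config.chrom_length - 10_000
        if n_here == 0:
            continue
        cell = (zone_hi - zone_lo) / n_here
        max_span = config.cluster_cpgs[1] * (config.background_spacing + 2)
        if cell < max_span + 1_400:
            raise ConfigError("background clusters too dense for the "
                              "intergenic zone; lower n_background_clusters")
        for i in range(n_here):
            n_cpg = int(rng_cpg.integers(config.cluster_cpgs[0],
                                         config.cluster_cpgs[1] + 1))
            start = int(zone_lo + i * cell
                        + rng_cpg.uniform(0, cell - max_span - 700))
            gaps = 2 + rng_cpg.geometric(1.0 / config.background_spacing,
                                         size=n_cpg)
            positions = start + np.concatenate([[0], np.cumsum(gaps[:-1])])
            for p in positions:
                cpg_rows.append([chrom, int(p), cluster_id, "background",
                                 pd.NA])
            background_clusters.append(cluster_id)
            cluster_id += 1

    cpgs = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "cluster_id",
                                           "kind", "gene_id"])
    cpgs = cpgs.sort_values(["chrom", "pos"]).reset_index(drop=True)

    # ---- plant DMRs -------------------------------------------------------
    by_cluster = cpgs.groupby("cluster_id").indices
    dmr_rows = []

    def _plant(cluster: int, width: int | None, delta: float, placement: str,
               gene_id, driver: bool = False) -> None:
        idx = np.sort(by_cluster[cluster])
        if width is None or width >= len(idx):
            member = idx
        else:
            off = (len(idx) - width) // 2
            member = idx[off:off + width]
        start = int(cpgs.loc[member[0], "pos"])
        end = int(cpgs.loc[member[-1], "pos"])
        chrom = cpgs.loc[member[0], "chrom"]
        dmr_rows.append([f"{chrom}:{start}-{end}", chrom, start, end,
                         len(member), delta,
                         "hyper" if delta > 0 else "hypo", placement, gene_id,
                         driver])

    driver_ids = set(drivers["gene_id"]) - nested
    for g in driver_ids:
        direction = drivers.loc[drivers["gene_id"] == g, "direction"].iloc[0]
        delta = config.driver_delta * (1 if direction == "hyper" else -1)
        cls = genes.loc[genes["gene_id"] == g, "promoter_class"].iloc[0]
        _plant(promoter_cluster[g], None, delta,
               f"{'poised' if cls == 'poised' else 'active' if cls == 'active' else 'other'}-promoter",
               g, driver=True)

    n_hyper = int(round(config.dmr_hyper_fraction * config.n_dmrs))
    n_hypo = config.n_dmrs - n_hyper
    used_genes = set(driver_ids)
    free_pools = {
        "poised-promoter": [g for g in genes.loc[
            genes["promoter_class"] == "poised", "gene_id"]
            if g not in used_genes],
        "active-promoter": [g for g in genes.loc[
            genes["promoter_class"] == "active", "gene_id"]
            if g not in used_genes],
    }
    rng_cpg.shuffle(free_pools["poised-promoter"])
    rng_cpg.shuffle(free_pools["active-promoter"])
    free_bg = list(background_clusters)
    rng_cpg.shuffle(free_bg)
    for direction, n_dir, fractions in (
            ("hyper", n_hyper, config.hyper_placement),
            ("hypo", n_hypo, config.hypo_placement)):
        delta = config.dmr_delta * (1 if direction == "hyper" else -1)
        for placement, count in _class_counts(n_dir, fractions).items():
            for _ in range(count):
                if placement == "intergenic":
                    if not free_bg:
                        raise ConfigError("not enough background clusters "
                                          "for planted intergenic DMRs")
                    _plant(free_bg.pop(), config.dmr_width_cpg, delta,
                           "intergenic", pd.NA)
                else:
                    pool = free_pools[placement]
                    if not pool:
                        pool = free_bg  # fall back to intergenic space
                        if not pool:
                            raise ConfigError("no free promoters left for "
                                              f"{placement} DMRs")
                        _plant(pool.pop(), config.dmr_width_cpg, delta,
                               "intergenic", pd.NA)
                        continue
                    g = pool.pop()
                    _plant(promoter_cluster[g], config.dmr_width_cpg, delta,
                           placement, g)
    dmrs = pd.DataFrame(dmr_rows, columns=["dmr_id", "chrom", "start", "end",
                                           "n_cpg", "delta", "direction",
                                           "placement", "gene_id",
                                           "is_driver"])
    truth = GroundTruth(dmrs=dmrs, drivers=drivers,
                        planted_tf=config.planted_tf
                        if config.n_tf_groups else None)

    # ---- CGIs -------------------------------------------------------------
    cgi_rows = []
    for g_id, cl in promoter_cluster.items():
        row = genes.loc[genes["gene_id"] == g_id].iloc[0]
        if row["promoter_class"] in ("poised", "active"):
            idx = np.sort(by_cluster[cl])
            cgi_rows.append([row["chrom"], int(cpgs.loc[idx[0], "pos"]) - 50,
                             int(cpgs.loc[idx[-1], "pos"]) + 50])
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])

    # ---- chromatin-state segmentations ------------------------------------
    rng_states = np.random.default_rng(s_states)
    esc_ids = [f"ESC{i + 1}" for i in range(config.n_esc)]
    tissue_ids = [f"LNG{i + 1}" for i in range(config.n_tissue)]
    bg_states = ["Quies", "Het", "Tx", "TxWk", "ReprPC"]
    bg_probs = [0.55, 0.15, 0.10, 0.10, 0.10]
    coding_genes = genes[(genes["biotype"] == "coding")]
    promoters = []
    for _, g in coding_genes.iterrows():
        tss = g["start"] if g["strand"] == "+" else g["end"]
        promoters.append((g["chrom"], max(1, tss - 2000), tss + 2000,
                          g["promoter_class"]))
    promoters.sort()
    states = {}
    for epi in esc_ids + tissue_ids:
        seg_rows = []
        is_esc = epi in esc_ids
        for chrom in chroms:
            cursor = 1
            for (c, ps, pe, cls) in [p for p in promoters if p[0] == chrom]:
                while cursor < ps:
                    seg_len = int(rng_states.integers(20_000, 80_000))
                    seg_end = min(cursor + seg_len - 1, ps - 1)
                    seg_rows.append([chrom, cursor,
                                     seg_end, rng_states.choice(bg_states,
                                                                p=bg_probs)])
                    cursor = seg_end + 1
                if is_esc:
                    core = {"poised": "TssBiv", "active": "TssA",
                            "other": "Quies"}[cls]
                    if rng_states.random() < config.state_flip_prob:
                        core = {"TssBiv": "TssA", "TssA": "TssBiv",
                                "Quies": "Het"}[core]
                else:
                    core = "TssA" if cls in ("poised", "active") else "Quies"
                flank = {"TssBiv": "BivFlnk", "TssA": "TssAFlnk"}.get(core)
                if flank is not None and pe - ps + 1 > 2_200:
                    # promoter core with its flanking state on both sides,
                    # as in real 15-state segmentations
                    seg_rows.append([chrom, ps, ps + 999, flank])
                    seg_rows.append([chrom, ps + 1000, pe - 1000, core])
                    seg_rows.append([chrom, pe - 999, pe, flank])
                else:
                    seg_rows.append([chrom, ps, pe, core])
                cursor = pe + 1
            while cursor <= config.chrom_length:
                seg_len = int(rng_states.integers(20_000, 80_000))
                seg_end = min(cursor + seg_len - 1, config.chrom_length)
                seg_rows.append([chrom, cursor, seg_end,
                                 rng_states.choice(bg_states, p=bg_probs)])
                cursor = seg_end + 1
        states[epi] = pd.DataFrame(seg_rows, columns=["chrom", "start", "end",
                                                      "state"])

    # ---- TF motif hits -----------------------------------------------------
    rng_m = np.random.default_rng(s_motifs)
    motif_rows = []
    tf_names = [f"TF{i + 1:02d}" for i in range(config.n_tf_groups)]
    driver_dmrs = dmrs[dmrs["is_driver"]]
    member_pos = {row["dmr_id"]: cpgs[(cpgs["chrom"] == row["chrom"])
                                      & (cpgs["pos"] >= row["start"])
                                      & (cpgs["pos"] <= row["end"])]["pos"]
                  .to_numpy() for _, row in dmrs.iterrows()}

    def _hit(tf, chrom, dmr_id) -> None:
        pos = member_pos[dmr_id]
        p = int(rng_m.choice(pos))
        motif_rows.append([tf, chrom, p - 4, p + 5])

    for tf in tf_names:
        for _, row in dmrs.iterrows():
            if rng_m.random() < config.background_motif_fraction:
                _hit(tf, row["chrom"], row["dmr_id"])
        for _ in range(10):  # scattered genome hits outside DMRs
            chrom = chroms[int(rng_m.integers(len(chroms)))]
            p = int(rng_m.integers(50_000, config.chrom_length - 50_000))
            motif_rows.append([tf, chrom, p, p + 9])
    if truth.planted_tf is not None and len(driver_dmrs):
        n_hit = int(round(config.planted_tf_interest_fraction
                          * len(driver_dmrs)))
        chosen = rng_m.choice(len(driver_dmrs), size=n_hit, replace=False)
        for i in chosen:
            row = driver_dmrs.iloc[i]
            _hit(truth.planted_tf, row["chrom"], row["dmr_id"])
    motifs = pd.DataFrame(motif_rows, columns=["tf", "chrom", "start", "end"])

    # ---- SNP blacklist -----------------------------------------------------
    rng_s = np.random.default_rng(s_snps)
    snp_rows = []
    n_on_cpg = min(config.n_snps // 2, len(cpgs))
    if n_on_cpg:
        on = rng_s.choice(len(cpgs), size=n_on_cpg, replace=False)
        for i in on:
            snp_rows.append([cpgs.loc[i, "chrom"], int(cpgs.loc[i, "pos"]),
                             int(cpgs.loc[i, "pos"])])
    for _ in range(config.n_snps - n_on_cpg):
        chrom = chroms[int(rng_s.integers(len(chroms)))]
        p = int(rng_s.integers(1, config.chrom_length))
        snp_rows.append([chrom, p, p])
    snps = pd.DataFrame(snp_rows, columns=["chrom", "start", "end"])

    ann = Annotation(chrom_sizes=chrom_sizes, genes=genes, cpgs=cpgs,
                     cgis=cgis, states=states, esc_ids=esc_ids,
                     tissue_ids=tissue_ids, motifs=motifs, snps=snps)
    return ann, truth


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _site_baselines(annotation: Annotation, truth: GroundTruth,
                    config: SimulationConfig,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-site baseline rate p0 and signed tumor shift."""
    cpgs = annotation.cpgs
    n = len(cpgs)
    is_promoter = (cpgs["kind"] == "promoter").to_numpy()
    p0 = np.where(is_promoter,
                  np.clip(rng.beta(*config.cgi_beta, size=n), 0.01, 0.60),
                  np.clip(rng.beta(*config.background_beta, size=n), 0.30,
                          0.99))
    shift = np.zeros(n)
    chroms = cpgs["chrom"].to_numpy()
    pos = cpgs["pos"].to_numpy()
    for _, d in truth.dmrs.iterrows():
        lo = np.searchsorted(chroms, d["chrom"], side="left")
        hi = np.searchsorted(chroms, d["chrom"], side="right")
        sub = pos[lo:hi]
        a = lo + np.searchsorted(sub, d["start"], side="left")
        b = lo + np.searchsorted(sub, d["end"], side="right")
        shift[a:b] = d["delta"]
        if d["delta"] > 0:   # realizable shift: low baseline for hyper ...
            p0[a:b] = rng.uniform(0.05, 0.25, size=b - a)
        else:                # ... and high baseline for hypo elements
            p0[a:b] = rng.uniform(0.55, 0.90, size=b - a)
    return p0, shift


def simulate_methylome(annotation: Annotation, truth: GroundTruth,
                       config: SimulationConfig) -> Methylome:
    ss = np.random.SeedSequence(config.seed).spawn(8)[6]
    rng = np.random.default_rng(ss)
    p0, shift = _site_baselines(annotation, truth, config, rng)

    n_sites = len(annotation.cpgs)
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    samples = [f"{p}T" for p in patients] + [f"{p}N" for p in patients]
    design = pd.DataFrame({
        "patient": patients * 2,
        "tissue": [TUMOR] * len(patients) + [NORMAL] * len(patients)},
        index=samples)

    n_samples = len(samples)
    is_tumor = np.array([1.0] * len(patients) + [0.0] * len(patients))
    p = (p0[:, None] + shift[:, None] * is_tumor[None, :]
         + rng.normal(0.0, config.sample_noise_sd, size=(n_sites, n_samples)))
    p = np.clip(p, 0.01, 0.99)

    if config.coverage_const is not None:
        cov = np.full((n_sites, n_samples), int(config.coverage_const))
    else:
        r = config.coverage_dispersion
        nb_p = r / (r + config.coverage_mean)
        cov = rng.negative_binomial(r, nb_p, size=(n_sites, n_samples))
        cov = np.maximum(cov, 1)
    meth = rng.binomial(cov, p)
    return Methylome(cpgs=annotation.cpgs, meth=meth, cov=cov, design=design)


# ---------------------------------------------------------------------------
# expression (+ probe cohorts)
# ---------------------------------------------------------------------------

def promoter_methylation(matrix: CpGMatrix, annotation: Annotation,
                         gene_ids=None) -> pd.DataFrame:
    """Mean rate over each gene's promoter CpG cluster, per sample.  Nested
    ncRNAs inherit the host promoter cluster."""
    genes = annotation.genes
    if gene_ids is None:
        gene_ids = list(genes["gene_id"])
    cpgs = annotation.cpgs
    rows = []
    for g in gene_ids:
        row = genes.loc[genes["gene_id"] == g].iloc[0]
        owner = row["host_gene"] if pd.notna(row["host_gene"]) else g
        sel = cpgs[(cpgs["gene_id"] == owner) & (cpgs["kind"] == "promoter")]
        if len(sel) == 0:
            raise ValueError(f"driver gene {g} lacks promoter CpGs")
        rows.append({"chrom": sel["chrom"].iloc[0],
                     "start": int(sel["pos"].min()),
                     "end": int(sel["pos"].max())})
    intervals = pd.DataFrame(rows, index=gene_ids)
    return matrix.region_methylation(intervals)


def simulate_expression(annotation: Annotation, truth: GroundTruth,
                        config: SimulationConfig,
                        methylome: Methylome) -> ExpressionMatrix:
    """Gene expression coupled to promoter methylation for planted drivers:
    ``log2 expr = baseline - slope * promoter_meth + noise``; non-drivers are
    independent of methylation."""
    ss = np.random.SeedSequence(config.seed).spawn(8)[7]
    rng = np.random.default_rng(ss)
    matrix = methylome.to_matrix()
    genes = annotation.genes
    gene_ids = list(genes["gene_id"])
    meth = promoter_methylation(matrix, annotation, gene_ids)
    meth_vals = np.nan_to_num(meth.to_numpy(), nan=0.5)

    lo, hi = config.expr_baseline_log2
    baselines = rng.uniform(lo, hi, size=len(gene_ids))
    driver_set = set(truth.drivers["gene_id"])
    slope = np.array([config.coupling_slope if g in driver_set else 0.0
                      for g in gene_ids])
    noise = rng.normal(0.0, config.expr_noise_sd,
                       size=(len(gene_ids), meth.shape[1]))
    log2_expr = baselines[:, None] - slope[:, None] * meth_vals + noise
    values = pd.DataFrame(np.power(2.0, log2_expr), index=gene_ids,
                          columns=meth.columns)
    return ExpressionMatrix(values, methylome.design)


def simulate_probe_cohort(annotation: Annotation, truth: GroundTruth,
                          config: SimulationConfig, name: str,
                          stream: int) -> ProbeCohort:
    """One array-style validation cohort: probe betas track promoter
    methylation, expression keeps the planted coupling; samples are
    independent of the discovery cohort and unpaired."""
    ss = np.random.SeedSequence(config.seed).spawn(12 + stream)[-1]
    rng = np.random.default_rng(ss)
    genes = annotation.genes
    coding = genes[genes["biotype"] == "coding"]
    cpgs = annotation.cpgs
    n_t, n_n = config.validation_n_tumor, config.validation_n_normal
    samples = ([f"{name}_T{i + 1:03d}" for i in range(n_t)]
               + [f"{name}_N{i + 1:03d}" for i in range(n_n)])
    labels = pd.Series([TUMOR] * n_t + [NORMAL] * n_n, index=samples)

    driver_dir = dict(zip(truth.drivers["gene_id"], truth.drivers["direction"]))
    meth_rows, expr_rows, probe_rows, beta_rows = [], [], [], []
    gene_ids = list(coding["gene_id"])
    for g in gene_ids:
        sel = cpgs[(cpgs["gene_id"] == g) & (cpgs["kind"] == "promoter")]
        base = 0.10 if g not in driver_dir else (
            0.12 if driver_dir[g] == "hyper" else 0.72)
        shift = 0.0
        if g in driver_dir:
            shift = config.driver_delta * (1 if driver_dir[g] == "hyper"
                                           else -1)
        m = np.clip(base + shift * (labels == TUMOR).to_numpy(dtype=float)
                    + rng.normal(0, 0.08, size=len(samples)), 0.01, 0.99)
        meth_rows.append(m)
        for k in range(config.probes_per_promoter):
            probe_id = f"{name}_probe_{g}_{k + 1}"
            pos = int(rng.choice(sel["pos"].to_numpy()))
            probe_rows.append([probe_id, sel["chrom"].iloc[0], pos])
            beta = np.clip(m + rng.normal(0, config.probe_noise_sd,
                                          size=len(samples)), 0.0, 1.0)
            miss = rng.random(len(samples)) < config.probe_missing_rate
            beta[miss] = np.nan
            beta_rows.append(beta)
    meth = np.asarray(meth_rows)
    baselines = rng.uniform(*config.expr_baseline_log2, size=len(gene_ids))
    slope = np.array([config.coupling_slope if g in driver_dir else 0.0
                      for g in gene_ids])
    noise = rng.normal(0, config.expr_noise_sd,
                       size=(len(gene_ids), len(samples)))
    expr = pd.DataFrame(np.power(2.0, baselines[:, None]
                                 - slope[:, None] * meth + noise),
                        index=gene_ids, columns=samples)
    betas = pd.DataFrame(np.asarray(beta_rows),
                         index=[r[0] for r in probe_rows], columns=samples)
    # one deliberately patchy probe exercises the >10%-missing filter
    if len(betas):
        patchy = betas.index[0]
        k = max(1, int(0.15 * len(samples)))
        betas.loc[patchy, betas.columns[:k]] = np.nan
    probe_positions = pd.DataFrame(probe_rows,
                                   columns=["probe_id", "chrom", "pos"])
    return ProbeCohort(name=name, betas=betas,
                       probe_positions=probe_positions, expr=expr,
                       labels=labels)


def simulate_marker_cohort(n_tumor: int = 50, n_normal: int = 50,
                           n_markers: int = 8, delta: float = 0.3,
                           n_null_genes: int = 12, noise_sd: float = 0.1,
                           base: float = 0.12,
                           seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Gene-level promoter methylation for an independent diagnostic
    cohort: ``n_markers`` marker genes gain ``delta`` methylation in
    tumors, null genes vary without any group effect.  Returns the
    genes-by-samples beta matrix and the tissue labels."""
    rng = np.random.default_rng(seed)
    samples = ([f"T{i + 1:03d}" for i in range(n_tumor)]
               + [f"N{i + 1:03d}" for i in range(n_normal)])
    labels = pd.Series([TUMOR] * n_tumor + [NORMAL] * n_normal,
                       index=samples)
    is_tumor = (labels == TUMOR).to_numpy(dtype=float)
    rows, index = [], []
    for i in range(n_markers):
        rows.append(np.clip(base + delta * is_tumor
                            + rng.normal(0, noise_sd, len(samples)),
                            0.0, 1.0))
        index.append(f"MK{i + 1:02d}")
    for i in range(n_null_genes):
        b = rng.uniform(0.1, 0.9)
        rows.append(np.clip(b + rng.normal(0, noise_sd, len(samples)),
                            0.0, 1.0))
        index.append(f"NU{i + 1:02d}")
    return pd.DataFrame(np.asarray(rows), index=index, columns=samples), labels


def simulate_dataset(config: SimulationConfig | None = None,
                     **overrides) -> SimulatedDataset:
    """Run the whole generator and bundle annotation, planted truth, the
    paired methylation matrix, expression and validation cohorts."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    annotation, truth = simulate_annotation(config)
    methylome = simulate_methylome(annotation, truth, config)
    matrix = methylome.to_matrix()
    expression = simulate_expression(annotation, truth, config, methylome)
    cohorts = {name: simulate_probe_cohort(annotation, truth, config, name, i)
               for i, name in enumerate(config.validation_cohorts)}
    return SimulatedDataset(config=config, annotation=annotation, truth=truth,
                            methylome=methylome, matrix=matrix,
                            expression=expression, cohorts=cohorts)
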