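# Methods

This note documents the models and procedures implemented in `methdriver`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not establish.

## Data model and conventions

All genomic coordinates are 1-based with both endpoints included
(`length = end − start + 1`); BED files are converted at the I/O boundary
(BED start `s` ↔ internal `s + 1`), making the conversion an exact inverse
pair.  Methylation rates and probe betas live in [0, 1]; missing values
are explicit NaN, never 0, because 0 is a valid rate.  The paired design
is a hard contract: every patient has exactly one tumor and one normal
sample, validated on construction of every matrix.

## Methylome QC

Sites enter the merged matrix when their rate (computed only at ≥ 5×
coverage) is observed in both tissues of at least 10 patients.
Heterosome (`chrX`/`chrY` by default, configurable) and SNP-overlapping
CpGs are removed; both filters are set subtractions and therefore commute.
Blacklisting runs before imputation — fewer sites to impute, and
blacklisted sites should never donate values.

KNN imputation works in CpG space: the missing entry of site *i* in sample
*s* becomes the mean over the *k* = 10 nearest sites (Euclidean distance
over commonly observed samples, rescaled to the full sample count) of
their observed values in *s*.  Sites sharing fewer than 3 observed samples
are not eligible neighbors; a site with no observed values at all is an
error.  Imputed values are means of rates and hence stay in [0, 1];
observed entries are never altered.  The distance computation is dense
(O(n²) in sites) and intended for the post-QC matrices and probe panels
this pipeline imputes, not for millions of sites at once; the DMR caller
itself is NaN-aware and does not require imputation.

"Most variable" sites are ranked by variance across all samples (not MAD);
the 10%/80% category boundaries are assigned to the intermediate class.
Clustering uses Ward linkage on Euclidean sample distances; the projection
is a centered PCA; both require a complete matrix.

## DMR calling

Candidate generation is deterministic segmentation, not a reimplementation
of any published caller binary.  Sites are pre-segmented into windows at
inter-CpG gaps > 300 bp (a CpG-cluster scale chosen here; exposed as
`max_gap_bp`) or chromosome changes; windows with < 10 CpGs are dropped.
Within a window the signal is the per-CpG mean paired difference.  The
sub-segment maximizing `|mean| · √length` (subject to ≥ 10 CpGs and
|mean| ≥ 0.10) is emitted and the flanks are segmented recursively — a
CBS-flavored objective whose √length weighting balances effect size
against region support.  Ties break leftmost, then longest.

Each candidate is tested by collapsing member CpGs to one mean per patient
per tissue and applying the two-sided paired Wilcoxon signed-rank test:
exact for ≤ 25 informative pairs via a dynamic program over doubled
average ranks (ties handled exactly; zeros dropped; < 3 non-zero
differences ⇒ p = 1 with a warning), normal approximation with
tie-corrected variance and continuity correction beyond.  Final calls
require all three gates jointly: ≥ 10 CpGs, |Δ| ≥ 0.10 and BH FDR < 0.05,
with BH computed over all candidates of a run.  Swapping tumor/normal
labels negates every Δ exactly.

## Chromatin-state annotation and enrichment

A feature annotates a DMR when it covers ≥ 50% of the DMR's bases
(boundary inclusive); features sharing a label are unioned first.
Promoters are TSS ± 2 kb with the strand-aware TSS, clipped at the
chromosome start.  A state is ESC-recurrent when annotated in at least
⌈n/2⌉ of the n ESC epigenomes; the most recurrent state wins and the rare
exact ties break by canonical 15-state order (real segmentations
essentially never tie; the rule only pins down determinism).

Fold enrichment is the odds-ratio form over base counts,
`F = (O/G) / ((D/G)(S/G)) = O·G/(D·S)`; it is undefined (an error) when
the DMR set or the state has zero bases, 0 when the overlap is empty, and
scale-invariant under joint rescaling of all four counts.  `G` is the sum
of the declared chromosome lengths.  Normalized scores `E_i = F_i/ΣF_j`
form a probability vector over the 15 states.  Hypermethylated promoter
DMRs are subtyped by their ESC-recurrent state: poised = {TssBiv,
BivFlnk}, active = {TssA, TssAFlnk} (both configurable); promoter DMRs
with another or no recurrent state get the extra label `promoter-other`
rather than being forced into either class.  Enrichment is computed per
epigenome and reported per epigenome, not averaged.

## Driver discovery and validation

Differential expression removes genes with 90th-quantile RPKM < 1, tests
`log2(RPKM+1)` with the paired t-test (zero-variance differences carry no
evidence, p = 1), adjusts by BH, and reports the linear fold change of
means.  The pseudocount-1 log transform is this package's choice.

Gene–DMR pairs require the DMR to overlap the gene promoter under the same
50% rule.  DMR methylation per sample is the mean rate over member CpGs;
Spearman ρ is computed across all samples jointly (tumor + normal pooled —
the correlation is driven by the tumor–normal contrast, which is the
signal of interest; a per-group option exists).  Exact permutation
p-values below ten samples, t-approximation otherwise; BH across all
pairs.  Per gene the most negative ρ wins (ties: smaller p, then leftmost
DMR).  Discovery gates: ρ < −0.3 (strict), pair FDR < 0.05, DE FDR < 0.05
and FC > 2 or < 0.5 — two-sided because hypomethylation drivers are
upregulated.  Direction: hyper-driver = methylation gain + downregulation;
hypo-driver = loss + upregulation; anything else is flagged inconsistent.

Validation cohorts are probe-beta matrices with expression for independent
(unpaired) samples.  Probes with > 10% missing betas are discarded, the
rest KNN-imputed in probe space; probes map to promoters by position; per
gene the probe with the most negative ρ is kept and the gene validates at
ρ < −0.3 with BH FDR < 0.05 across the tested genes.  Genes without any
promoter probe are untestable and excluded from the BH family.  Tiers:
high = validated in every cohort, moderate = in at least one, primary =
discovery only; tiering is monotone by construction.  ncRNA drivers run
through the identical functions with lncRNA/miRNA gene models and carry
their biotype; ncRNA/host co-regulation requires both to be driver calls
whose chosen DMR id is literally the same promoter DMR.

## TF motifs

The motif unit is the region: a DMR either contains ≥ 1 hit of a TF group
or it does not.  Enrichment of the interest set (driver promoter DMRs)
against the background (all called DMRs) is the hypergeometric upper tail
with N = background size, K = interest size, n = background DMRs with a
hit, k = interest DMRs with a hit, BH across TF groups.  The activity
score `y = ρ·log2(FC)` uses the methylation–expression ρ of the target's
DMR; y > 0 iff ρ and log2(FC) share sign, so silenced targets
(ρ < 0, FC < 1) score positive.  Multiple binding sites average
arithmetically.  The hyper-versus-hypo comparison is a two-sided Fisher
test on the 2×2 table (enriched vs not, per direction) over the TF-group
universe; the table is reported explicitly because other constructions are
defensible.

## Marker-panel evaluation

Half splits are stratified per class (train gets ⌈n/2⌉ overall) and
deterministic under the seed; a single-sample class cannot be split.  The
default scorer is a 200-tree random forest fit on the train split only —
the leakage test asserts that scrambling test labels leaves the scores
bit-identical — with a fitting-free mean-methylation scorer as baseline.
ROC/AUC comes from the standard threshold sweep; with ties it equals the
rank-average Mann–Whitney `U/(n1·n2)`, an identity the tests verify.  The
bootstrap CI resamples samples with replacement (2,000 draws by default).

## Synthetic data generator

The generator emulates the study design the pipeline targets: 18 paired
tumor/normal samples by default.  CpGs occur in clusters — one ~30-CpG
cluster (≈ 15 bp spacing) per gene promoter with CGI-like low baselines
(Beta(0.5, 10)), plus intergenic background clusters (≈ 25 bp spacing)
with high baselines (Beta(10, 0.5)) — reproducing the bimodal methylome
and giving the pre-segmentation natural window boundaries.  Coverage is
negative binomial (mean 30, dispersion 5, truncated at 1; RRBS-like
overdispersion) and methylated counts are binomial with a per-site,
per-sample rate jittered by N(0, 0.05) around the baseline.

Planted DMRs shift the tumor rate by ±Δ (default 0.4) over a block of
CpGs; generic DMRs are 15 CpGs wide and placed by class (hyper: 46%
poised-promoter, 11% active-promoter, rest intergenic; hypo mostly
intergenic), while driver DMRs span the gene's whole promoter cluster so
that the coupling covariate — promoter mean methylation — and the planted
regulatory element coincide.  Block baselines are drawn
direction-compatible (U(0.05, 0.25) for hyper, U(0.55, 0.90) for hypo) so
the planted shift is realizable inside [0, 1].  Driver expression follows
`log2 expr = baseline − slope · promoter_meth + N(0, σ)` with slope 4 and
σ = 0.5; non-drivers are independent of methylation.  Validation cohorts
draw new unpaired samples whose probe betas track promoter methylation
with array-like noise (σ = 0.05, 2% missingness, plus one deliberately
patchy probe to exercise the 10% filter).  ESC segmentations tile each
chromosome completely: promoter cores (TssBiv for poised genes, TssA for
active, 10% flips) flanked by 1 kb BivFlnk/TssAFlnk segments — as in real
15-state maps, where flanking states surround every promoter core — over
a Quies/Het/Tx background.  Motif hits for the planted TF land in 60% of
driver promoter DMRs versus ~5% of all planted DMRs for every TF group.
One seed determines everything through per-stage spawned substreams;
regeneration is byte-identical.

What the simulations do **not** model: read-level artifacts (bisulfite
conversion error, mapping bias, strand asymmetry), copy-number and purity
effects, spatial correlation of methylation beyond block structure,
batch effects, and realistic genome scale.  Passing the planted-truth
benchmarks therefore shows that the algorithms recover the effects they
are specified to detect under controlled noise — not that real-data
performance at genome scale will match.

## Benchmark problem sizes

The replicate benchmarks in `methdriver.experiments` (shared by the
acceptance tests and `scripts/acceptance.py`) use: 20 replicate seeds per
benchmark; for the DMR caller a ~50,000-CpG genome (two 12-Mb
chromosomes, ~1,450 background clusters) with 50 planted DMRs plus a
matched null genome; for the funnel the default dataset (two 4-Mb
chromosomes, ~6,300 CpGs, 60 coding genes with 20 hyper + 11 hypo planted
drivers, 12 lncRNAs and 8 miRNAs with 13 planted ncRNA drivers, 20 TF
groups, two 80-sample validation cohorts); for the panel a 100-sample
cohort with 8 planted markers at Δ = 0.3.  These sizes keep a full run in
a few minutes while leaving every statistical gate non-trivially exercised
(e.g. the BH families contain dozens to hundreds of tests).

## Known limitations

- The segmentation objective and the 300 bp gap are reasonable defaults,
  not fitted to any reference caller; regions from other callers can be
  fed directly into `call_dmrs` as candidates.
- Exact Spearman permutation p-values are only computed below ten samples;
  all study-scale correlations use the t-approximation.
- The dense KNN imputer is quadratic in sites and meant for post-QC or
  probe-scale matrices.
- `fold_enrichment` treats the genome size as given; declared chromosome
  lengths must be consistent with the interval sets.
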