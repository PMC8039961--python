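"""Shared genomic containers and coordinate conventions.

All coordinates are 1-based and inclusive on both ends; BED I/O converts at
the boundary (see :mod:`methdriver.io`).  Methylation rates live in [0, 1]
and missing values are always an explicit NaN -- zero is a valid rate and is
never used as a missing-data sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
TISSUES = (TUMOR, NORMAL)

#: Default set of sex ("heterosome") chromosome names.
DEFAULT_SEX_CHROMS = frozenset({"chrX", "chrY"})

#: Columns of a gene-model table (GTF-lite TSV).
GENE_MODEL_COLUMNS = ("gene_id", "chrom", "start", "end", "strand",
                      "biotype", "host_gene")

BIOTYPES = ("coding", "lncRNA", "miRNA")


class DesignError(ValueError):
    """Sample sheet violates the paired tumor/normal contract."""


class ParseError(ValueError):
    """A text input could not be parsed; the message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 1-based with both endpoints included.

    ``length == end - start + 1``; a single base has ``start == end``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"interval end < start: "
                             f"{self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __str__(self) -> str:  # used as DMR/feature identifier
        return f"{self.chrom}:{self.start}-{self.end}"


def validate_design(design: pd.DataFrame) -> None:
    """Check the paired design sheet: index = sample ids, columns
    ``patient`` and ``tissue``; every patient has exactly one tumor and one
    normal sample."""
    for col in ("patient", "tissue"):
        if col not in design.columns:
            raise DesignError(f"design sheet lacks required column {col!r}")
    bad = set(design["tissue"]) - set(TISSUES)
    if bad:
        raise DesignError(f"unknown tissue labels: {sorted(bad)}")
    counts = design.groupby(["patient", "tissue"]).size().unstack(fill_value=0)
    for tissue in TISSUES:
        if tissue not in counts.columns:
            counts[tissue] = 0
    off = counts[(counts[TUMOR] != 1) | (counts[NORMAL] != 1)]
    if len(off):
        raise DesignError(
            "each patient needs exactly one tumor and one normal sample; "
            f"violated by patients {list(off.index)}")


class CpGMatrix:
    """Per-CpG, per-sample methylation rates under a paired design.

    Parameters
    ----------
    rates : DataFrame
        Index is a ``(chrom, pos)`` MultiIndex sorted lexicographically;
        columns are sample ids; values are rates in [0, 1] or NaN (missing).
    design : DataFrame
        Index sample ids, columns ``patient`` and ``tissue``.
    """

    def __init__(self, rates: pd.DataFrame, design: pd.DataFrame):
        validate_design(design)
        missing = set(rates.columns) - set(design.index)
        if missing:
            raise DesignError(f"samples without design rows: {sorted(missing)}")
        design = design.loc[list(rates.columns)]
        vals = rates.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValueError("methylation rates must lie in [0, 1]")
        if not rates.index.is_monotonic_increasing:
            rates = rates.sort_index()
        self.rates = rates
        self.design = design

    # -- design helpers ---------------------------------------------------
    @property
    def patients(self) -> list:
        return sorted(self.design["patient"].unique())

    def sample_of(self, patient, tissue: str) -> str:
        sel = self.design[(self.design["patient"] == patient)
                          & (self.design["tissue"] == tissue)]
        return sel.index[0]

    def _cols(self, tissue: str) -> list:
        return [self.sample_of(p, tissue) for p in self.patients]

    @property
    def tumor_samples(self) -> list:
        return self._cols(TUMOR)

    @property
    def normal_samples(self) -> list:
        return self._cols(NORMAL)

    # -- basic shape ------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.rates)

    @property
    def n_samples(self) -> int:
        return self.rates.shape[1]

    @property
    def chroms(self) -> np.ndarray:
        return self.rates.index.get_level_values(0).to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.rates.index.get_level_values(1).to_numpy()

    # -- derived quantities -----------------------------------------------
    def paired_diff(self) -> pd.DataFrame:
        """Per-site, per-patient tumor minus normal rate (NaN if either
        tissue is missing)."""
        t = self.rates[self.tumor_samples].to_numpy()
        n = self.rates[self.normal_samples].to_numpy()
        return pd.DataFrame(t - n, index=self.rates.index, columns=self.patients)

    def paired_delta(self) -> np.ndarray:
        """Per-site mean paired difference over patients (NaN-aware)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.paired_diff().to_numpy(), axis=1)

    def subset(self, mask) -> "CpGMatrix":
        return CpGMatrix(self.rates.loc[mask] if not isinstance(mask, np.ndarray)
                         else self.rates[mask], self.design)

    def swap_labels(self) -> "CpGMatrix":
        """Return a matrix with tumor/normal labels exchanged (used by the
        antisymmetry checks)."""
        design = self.design.copy()
        design["tissue"] = design["tissue"].map({TUMOR: NORMAL, NORMAL: TUMOR})
        return CpGMatrix(self.rates, design)

    def region_methylation(self, intervals: pd.DataFrame) -> pd.DataFrame:
        """Mean rate over member CpGs for each interval (rows) and sample
        (columns).  ``intervals`` needs chrom/start/end columns; row order is
        preserved and the index is kept."""
        out = np.full((len(intervals), self.n_samples), np.nan)
        vals = self.rates.to_numpy()
        chroms, poss = self.chroms, self.positions
        for i, (c, s, e) in enumerate(zip(intervals["chrom"], intervals["start"],
                                          intervals["end"])):
            lo, hi = _span_indices(chroms, poss, c, s, e)
            if hi > lo:
                with np.errstate(invalid="ignore"):
                    out[i] = np.nanmean(vals[lo:hi], axis=0)
        return pd.DataFrame(out, index=intervals.index, columns=self.rates.columns)


def _span_indices(chroms: np.ndarray, positions: np.ndarray,
                  chrom: str, start: int, end: int) -> tuple[int, int]:
    """Half-open index range of sorted (chrom, pos) site arrays falling in
    ``chrom:start-end`` (inclusive coordinates)."""
    lo_c = np.searchsorted(chroms, chrom, side="left")
    hi_c = np.searchsorted(chroms, chrom, side="right")
    sub = positions[lo_c:hi_c]
    lo = lo_c + int(np.searchsorted(sub, start, side="left"))
    hi = lo_c + int(np.searchsorted(sub, end, side="right"))
    return lo, hi


class ExpressionMatrix:
    """Feature-by-sample expression (RPKM for genes, RPM for miRNAs) on the
    linear scale, with the same paired-design contract as :class:`CpGMatrix`
    when ``design`` is given."""

    def __init__(self, values: pd.DataFrame, design: pd.DataFrame | None = None,
                 log2: bool = False):
        if not log2 and (values.to_numpy(dtype=float) < 0).any():
            raise ValueError("linear-scale expression must be non-negative")
        if design is not None:
            validate_design(design)
            missing = set(values.columns) - set(design.index)
            if missing:
                raise DesignError(f"samples without design rows: {sorted(missing)}")
            design = design.loc[list(values.columns)]
        self.values = values
        self.design = design
        self.log2 = log2

    @property
    def patients(self) -> list:
        return sorted(self.design["patient"].unique())

    def _cols(self, tissue: str) -> list:
        d = self.design
        return [d[(d["patient"] == p) & (d["tissue"] == tissue)].index[0]
                for p in self.patients]

    @property
    def tumor_samples(self) -> list:
        return self._cols(TUMOR)

    @property
    def normal_samples(self) -> list:
        return self._cols(NORMAL)


def gene_tss(genes: pd.DataFrame) -> pd.Series:
    """Strand-aware transcription start site: ``start`` on '+', ``end`` on '-'."""
    return pd.Series(np.where(genes["strand"] == "+", genes["start"],
                              genes["end"]), index=genes.index, name="tss")


def gene_tes(genes: pd.DataFrame) -> pd.Series:
    """Strand-aware transcript end site (opposite end from the TSS)."""
    return pd.Series(np.where(genes["strand"] == "+", genes["end"],
                              genes["start"]), index=genes.index, name="tes")
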