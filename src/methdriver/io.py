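"""Readers and writers for the plain-text formats every stage touches.

Interval files are standard BED (0-based, half-open); internally everything
is 1-based inclusive, so a BED row ``(chrom, s, e)`` becomes the interval
``chrom:s+1-e`` and the conversion is an exact inverse pair.  Tabular files
are TSV with a header line starting ``#``.
"""

from __future__ import annotations

import io as _io
from typing import Iterable

import numpy as np
import pandas as pd

from .core import GENE_MODEL_COLUMNS, GenomicInterval, ParseError

_BED_COLS = ("chrom", "start", "end", "name", "score", "strand")


# ---------------------------------------------------------------------------
# CpG count tables
# ---------------------------------------------------------------------------

def read_cpg_table(path, coverage_min: int = 5) -> pd.Series:
    """Read one sample's CpG count table (chrom, pos, methylated count C,
    total count N) and return rates ``C/N`` indexed by (chrom, pos).

    Sites with ``N < coverage_min`` get NaN (insufficient coverage); rows are
    sorted by coordinate.  Raises :class:`ParseError` naming the offending
    line on malformed input and ``ValueError`` when ``C > N``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, "
                                 f"got {len(parts)}")
            chrom = parts[0]
            try:
                pos, c, n = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field "
                                 f"({exc})") from None
            if c < 0 or n < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if c > n:
                raise ValueError(f"{path}:{lineno}: methylated count {c} "
                                 f"exceeds total {n}")
            rows.append((chrom, pos, c, n))
    if not rows:
        return pd.Series(dtype=float,
                         index=pd.MultiIndex.from_arrays([[], []],
                                                         names=["chrom", "pos"]))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "C", "N"])
    df = df.sort_values(["chrom", "pos"])
    rate = np.where(df["N"] >= coverage_min, df["C"] / df["N"].where(df["N"] > 0),
                    np.nan)
    return pd.Series(rate, index=pd.MultiIndex.from_frame(df[["chrom", "pos"]]))


def write_cpg_table(counts: pd.DataFrame, path) -> None:
    """Write a per-sample count table (columns chrom, pos, C, N)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tC\tN\n")
        counts.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals_bed(path) -> pd.DataFrame:
    """Read a BED file into a frame of internal 1-based inclusive intervals.

    Returns columns chrom/start/end plus name/score/strand and any extra
    columns present.  BED rows with ``end <= start`` are rejected.
    """
    rows = []
    extra_n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer BED "
                                 "coordinates") from None
            if e <= s:
                raise ValueError(f"{path}:{lineno}: BED end {e} <= start {s}")
            extra_n = max(extra_n, len(parts) - 6)
            rows.append([parts[0], s + 1, e] + parts[3:])
    cols = list(_BED_COLS)
    if extra_n > 0:
        cols += [f"extra{i}" for i in range(1, extra_n + 1)]
    if not rows:
        return pd.DataFrame(columns=cols[:3])
    width = max(len(r) for r in rows)
    rows = [r + [None] * (width - len(r)) for r in rows]
    df = pd.DataFrame(rows, columns=cols[:width])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_intervals_bed(intervals: pd.DataFrame, path,
                        extra_cols: Iterable[str] = ()) -> None:
    """Write internal intervals back to BED (start-1, end)."""
    cols = [c for c in ("name", "score", "strand") if c in intervals.columns]
    cols += [c for c in extra_cols if c in intervals.columns]
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend" + ("\t" + "\t".join(cols) if cols else "")
                 + "\n")
        for _, row in intervals.iterrows():
            fields = [row["chrom"], str(int(row["start"]) - 1),
                      str(int(row["end"]))]
            fields += [str(row[c]) for c in cols]
            fh.write("\t".join(fields) + "\n")


def as_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    """Convert an interval frame to :class:`GenomicInterval` objects."""
    strands = df["strand"] if "strand" in df.columns else ["."] * len(df)
    return [GenomicInterval(c, int(s), int(e), st if st in ("+", "-") else ".")
            for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strands)]


# ---------------------------------------------------------------------------
# DMRs
# ---------------------------------------------------------------------------

def write_dmrs_bed(dmrs, path) -> None:
    """Write called DMRs as BED6+ (name=direction, score=|delta| scaled to
    0-1000, extra columns n_cpg, delta, p, q)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tn_cpg\tdelta\tp\tq\n")
        for d in dmrs:
            fh.write("\t".join([
                d.interval.chrom, str(d.interval.start - 1), str(d.interval.end),
                d.direction, str(int(round(min(1.0, abs(d.delta)) * 1000))), ".",
                str(d.n_cpg), f"{d.delta:.6g}", f"{d.p_value:.6g}",
                f"{d.q_value:.6g}"]) + "\n")


def read_dmrs_bed(path) -> pd.DataFrame:
    """Read a DMR BED written by :func:`write_dmrs_bed` (internal coords)."""
    df = read_intervals_bed(path)
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "direction",
                                     "n_cpg", "delta", "p", "q"])
    out = df.rename(columns={"name": "direction", "extra1": "n_cpg",
                             "extra2": "delta", "extra3": "p", "extra4": "q"})
    out["n_cpg"] = out["n_cpg"].astype(int)
    for c in ("delta", "p", "q"):
        out[c] = out[c].astype(float)
    return out[["chrom", "start", "end", "direction", "n_cpg", "delta", "p", "q"]]


# ---------------------------------------------------------------------------
# Generic TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path, **kw) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().lstrip("#").rstrip("\n")
        body = fh.read()
    return pd.read_csv(_io.StringIO(first + "\n" + body), sep="\t", **kw)


def _write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write("#")
        df.to_csv(fh, sep="\t", index=index)


def read_gene_models(path) -> pd.DataFrame:
    """Read a GTF-lite gene-model TSV (gene_id, chrom, start, end, strand,
    biotype, host_gene)."""
    df = _read_tsv(path, dtype={"host_gene": "string"})
    missing = set(GENE_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: gene model table lacks columns "
                         f"{sorted(missing)}")
    return df


def write_gene_models(genes: pd.DataFrame, path) -> None:
    _write_tsv(genes[list(GENE_MODEL_COLUMNS)], path)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Feature-by-sample numeric matrix, first column the feature id."""
    df = _read_tsv(path)
    return df.set_index(df.columns[0])


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    _write_tsv(df, path, index=True)


def read_design(path) -> pd.DataFrame:
    df = _read_tsv(path)
    return df.set_index(df.columns[0])


def write_design(design: pd.DataFrame, path) -> None:
    _write_tsv(design, path, index=True)


def read_state_bed(path) -> pd.DataFrame:
    """Chromatin-state segmentation BED; the name column is the state
    mnemonic (TssA ... Quies)."""
    df = read_intervals_bed(path)
    return df.rename(columns={"name": "state"})[["chrom", "start", "end",
                                                 "state"]]


def read_motif_bed(path) -> pd.DataFrame:
    """Motif-hit BED; the name column is the TF-group label."""
    df = read_intervals_bed(path)
    return df.rename(columns={"name": "tf"})[["chrom", "start", "end", "tf"]]
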