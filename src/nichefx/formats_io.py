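"""Readers and writers for the on-disk formats the pipeline touches.

All genomic coordinates are handled internally as 0-based half-open
intervals.  Formats that are conventionally 1-based (the bismark-like
methylation coverage dialect) are converted at the boundary; the conversion
is logged once per process.

Readers validate strictly and raise :class:`FormatError` rather than
coercing malformed input.  Every writer emits a ``#`` header comment naming
the format and version, and its output is re-readable by the corresponding
reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("nichefx.formats_io")

FORMAT_VERSION = "1.0"

AGE_LEVELS = ("young", "aged")
TIME_LEVELS = ("T0", "T21")

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand", "summit")
METH_COLUMNS = ("chrom", "pos", "strand", "context", "count_methylated", "count_total")


class FormatError(ValueError):
    """A file violated its format contract (never silently coerced)."""


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def validate_counts(df: pd.DataFrame, where: str = "counts") -> pd.DataFrame:
    """Validate a genes x samples count frame: unique ids, non-negative ints."""
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{where}: duplicate gene_id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{where}: duplicate sample_id {dup!r}")
    if df.isna().any().any():
        raise FormatError(f"{where}: NA values are not allowed")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{where}: non-numeric values present")
    if np.any(arr != np.floor(arr)):
        g, s = np.argwhere(arr != np.floor(arr))[0]
        raise FormatError(
            f"{where}: non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if np.any(arr < 0):
        g, s = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{where}: negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return df.astype(np.int64)


def read_counts(path) -> pd.DataFrame:
    """Read a TSV count matrix (first column gene_id, one column per sample)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return validate_counts(df, where=str(path))


def write_counts(counts: pd.DataFrame, path) -> None:
    counts = validate_counts(counts)
    counts = counts.sort_index(kind="stable")
    with open(path, "w") as fh:
        fh.write(f"# nichefx counts v{FORMAT_VERSION}\n")
        counts.to_csv(fh, sep="\t", index_label="gene_id")


def read_counts_mtx(mtx_path, genes_path, samples_path) -> pd.DataFrame:
    """Read a MatrixMarket count matrix with side files of gene/sample ids.

    Provided for interoperability; TSV is the native format for these small
    bulk matrices.
    """
    from scipy import io as spio

    mat = spio.mmread(mtx_path)
    genes = [line.split("\t")[0] for line in Path(genes_path).read_text().splitlines() if line]
    samples = [line.strip() for line in Path(samples_path).read_text().splitlines() if line]
    arr = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    if arr.shape != (len(genes), len(samples)):
        raise FormatError(
            f"{mtx_path}: matrix shape {arr.shape} does not match "
            f"{len(genes)} genes x {len(samples)} samples"
        )
    df = pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"), columns=samples)
    return validate_counts(df, where=str(mtx_path))


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

def validate_design(design: pd.DataFrame, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    required = {"sample_id", "age", "time", "batch"}
    missing = required - set(design.columns)
    if missing:
        raise FormatError(f"design: missing columns {sorted(missing)}")
    design = design.copy()
    design["sample_id"] = design["sample_id"].astype(str)
    if design["sample_id"].duplicated().any():
        raise FormatError("design: duplicate sample_id")
    for col, levels in (("age", AGE_LEVELS), ("time", TIME_LEVELS)):
        bad = set(design[col]) - set(levels)
        if bad:
            raise FormatError(f"design: unknown {col} level(s) {sorted(bad)}; expected {levels}")
    design["batch"] = design["batch"].astype(str)
    if counts is not None:
        want = [str(c) for c in counts.columns]
        have = set(design["sample_id"])
        absent = [s for s in want if s not in have]
        if absent:
            raise FormatError(f"design: missing sample(s) {absent} present in counts")
        design = design.set_index("sample_id").loc[want].reset_index()
    return design


def read_design(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read the sample-design TSV and (optionally) align rows to count columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return validate_design(df, counts)


def write_design(design: pd.DataFrame, path) -> None:
    design = validate_design(design)
    with open(path, "w") as fh:
        fh.write(f"# nichefx design v{FORMAT_VERSION}\n")
        design.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def validate_intervals(df: pd.DataFrame, where: str = "bed") -> pd.DataFrame:
    df = df.copy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    if np.any(starts < 0):
        raise FormatError(f"{where}: negative start coordinate")
    bad = np.argwhere(starts >= ends)
    if bad.size:
        i = bad[0, 0]
        raise FormatError(
            f"{where}: start >= end at {df['chrom'].iloc[i]}:{starts[i]}-{ends[i]}"
        )
    if "strand" in df.columns:
        unknown = set(df["strand"].dropna()) - {"+", "-", "."}
        if unknown:
            raise FormatError(f"{where}: invalid strand value(s) {sorted(unknown)}")
    return df


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6(+summit col 7); coordinates are 0-based half-open."""
    rows = []
    ncols = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with < 3 fields")
            ncols = max(ncols, len(parts))
            rows.append(parts)
    if not rows:
        return pd.DataFrame(columns=list(BED_COLUMNS[:3]))
    ncols = min(ncols, len(BED_COLUMNS))
    cols = list(BED_COLUMNS[:ncols])
    rows = [r[:ncols] + [None] * (ncols - len(r)) for r in rows]
    df = pd.DataFrame(rows, columns=cols)
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer BED coordinate ({exc})") from None
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"].replace(".", "0"))
    if "summit" in df.columns:
        df["summit"] = df["summit"].astype(np.int64)
    return validate_intervals(df, where=str(path))


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals = validate_intervals(intervals)
    cols = [c for c in BED_COLUMNS if c in intervals.columns]
    out = intervals[cols].copy()
    if "strand" in cols:  # BED requires name/score when strand is present
        for filler, default in (("name", "."), ("score", 0)):
            if filler not in cols:
                out[filler] = default
        out = out[[c for c in BED_COLUMNS if c in out.columns]]
    with open(path, "w") as fh:
        fh.write(f"# nichefx bed v{FORMAT_VERSION}\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# methylation tables (bismark-coverage-like dialect, positions 1-based on disk)
# ---------------------------------------------------------------------------

_meth_conversion_logged = False


def read_methylation(path) -> pd.DataFrame:
    """Read a per-CpG methylation table.

    On-disk columns: chrom, pos (1-based), strand, context, count_methylated,
    count_total.  The returned frame carries ``pos0`` (0-based).
    """
    global _meth_conversion_logged
    df = pd.read_csv(
        path, sep="\t", comment="#", names=list(METH_COLUMNS), dtype={"chrom": str}
    )
    for col in ("pos", "count_methylated", "count_total"):
        if df[col].isna().any() or (df[col] != np.floor(df[col])).any():
            raise FormatError(f"{path}: non-integer {col}")
        df[col] = df[col].astype(np.int64)
    if (df["pos"] < 1).any():
        raise FormatError(f"{path}: 1-based position < 1")
    bad = df["count_methylated"] > df["count_total"]
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise FormatError(
            f"{path}: count_methylated > count_total at "
            f"{df['chrom'].iloc[i]}:{df['pos'].iloc[i]}"
        )
    df["pos0"] = df["pos"] - 1
    if not _meth_conversion_logged:
        logger.info("methylation positions converted 1-based -> 0-based on read")
        _meth_conversion_logged = True
    return df.drop(columns=["pos"])


def write_methylation(track: pd.DataFrame, path) -> None:
    """Write a methylation track (internal 0-based ``pos0`` -> 1-based on disk)."""
    out = track.copy()
    out["pos"] = out["pos0"] + 1
    out = out[list(METH_COLUMNS)]
    with open(path, "w") as fh:
        fh.write(f"# nichefx methylation v{FORMAT_VERSION} (pos 1-based)\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> pd.DataFrame:
    """Read bedGraph (chrom, start, end, value; 0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return validate_intervals(df, where=str(path))


def write_bedgraph(cov: pd.DataFrame, path) -> None:
    cov = validate_intervals(cov)
    with open(path, "w") as fh:
        fh.write(f"# nichefx bedgraph v{FORMAT_VERSION}\n")
        cov[["chrom", "start", "end", "value"]].to_csv(fh, sep="\t", header=False, index=False)


def coverage_vectors(cov: pd.DataFrame, chrom_lengths: dict[str, int] | None = None):
    """Expand a bedGraph frame into dense per-base vectors per chromosome."""
    vectors: dict[str, np.ndarray] = {}
    for chrom, sub in cov.groupby("chrom", sort=True):
        length = (
            chrom_lengths[chrom] if chrom_lengths is not None else int(sub["end"].max())
        )
        vec = np.zeros(length, dtype=float)
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            vec[start:min(end, length)] = value
        vectors[str(chrom)] = vec
    return vectors
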