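"""Readers and writers for methylation calls, manifests, BED annotations and
tile matrices.

Conventions: tab-separated text, 0-based half-open coordinates, methylation
stored as counts (coverage, n_meth) so that downstream tests can pool them;
fractions appear only in derived tile matrices and reports.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CALL_COLUMNS = ["chrom", "pos", "strand", "coverage", "n_meth"]
MANIFEST_COLUMNS = ["sample_id", "timepoint", "replicate"]

BED_DIALECTS = {
    "bed4": ["chrom", "start", "end", "name"],
    "bed6": ["chrom", "start", "end", "name", "score", "strand"],
    "bed6+feature": ["chrom", "start", "end", "name", "score", "strand", "feature"],
    "bed6+class": ["chrom", "start", "end", "name", "score", "strand", "repeat_class"],
}


class CallFormatError(ValueError):
    """A methylation call table violates the format or its invariants."""


def write_calls(calls: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    calls[CALL_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read and validate a methylation call TSV.

    Returns the table sorted by (chrom, pos).  Raises
    :class:`CallFormatError` on missing columns, non-numeric fields (with the
    offending line number), n_meth > coverage (naming the row), or duplicate
    (chrom, pos, strand) entries.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise CallFormatError(f"{path}: missing columns {missing}")
    df = df[CALL_COLUMNS]
    if df.empty:
        return df.assign(pos=[], coverage=[], n_meth=[]).astype(
            {"pos": int, "coverage": int, "n_meth": int}
        )
    for col in ("pos", "coverage", "n_meth"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.astype("Int64").astype(float))
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise CallFormatError(
                f"{path}: malformed value in column {col!r} at line {line}"
            )
        df[col] = converted.astype(int)
    if (df["coverage"] < 0).any():
        row = df.index[df["coverage"] < 0][0]
        raise CallFormatError(f"{path}: negative coverage at row {row}")
    bad = df["n_meth"] > df["coverage"]
    if bad.any():
        r = df.loc[bad.idxmax()]
        raise CallFormatError(
            f"{path}: n_meth ({r.n_meth}) > coverage ({r.coverage}) at "
            f"{r.chrom}:{r.pos} ({r.strand})"
        )
    if (df["n_meth"] < 0).any():
        row = df.index[df["n_meth"] < 0][0]
        raise CallFormatError(f"{path}: negative n_meth at row {row}")
    dup = df.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        r = df.loc[dup.idxmax()]
        raise CallFormatError(
            f"{path}: duplicate call at {r.chrom}:{r.pos} ({r.strand})"
        )
    return df.sort_values(["chrom", "pos"], ignore_index=True)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = MANIFEST_COLUMNS + (["path"] if "path" in manifest.columns else [])
    manifest[cols].to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "timepoint": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_ids in manifest")
    if "path" in df.columns and check_files:
        for p in df["path"]:
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file {p}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path, dialect: str) -> Path:
    if dialect not in BED_DIALECTS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    cols = BED_DIALECTS[dialect]
    path = Path(path)
    df[cols].to_csv(path, sep="\t", index=False, header=False)
    return path


def read_bed(path: str | Path, dialect: str) -> pd.DataFrame:
    """Read a BED file of the given dialect into a per-chromosome sorted
    DataFrame of 0-based half-open intervals."""
    if dialect not in BED_DIALECTS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    cols = BED_DIALECTS[dialect]
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols,
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=cols)
    if df.empty:
        return df.astype({"start": int, "end": int}, errors="ignore")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df["start"] >= df["end"]
    if bad.any():
        r = df.loc[bad.idxmax()]
        raise ValueError(
            f"{path}: invalid interval {r.chrom}:{r.start}-{r.end} (start >= end)"
        )
    return df.sort_values(["chrom", "start", "end"], ignore_index=True)


def write_tile_matrix(matrix, path: str | Path) -> Path:
    """Write a TileMatrix as one TSV: coordinates, n_cpg, then per sample the
    methylation fraction, mean coverage, and pooled counts (lossless)."""
    path = Path(path)
    out = matrix.tiles.copy()
    for s in matrix.samples:
        out[f"meth_{s}"] = matrix.meth[s]
        out[f"cov_{s}"] = matrix.mean_cov[s]
        out[f"methreads_{s}"] = matrix.meth_counts[s]
        out[f"totreads_{s}"] = matrix.total_counts[s]
        out[f"ncpg_{s}"] = matrix.n_cpg[s]
    out.to_csv(path, sep="\t", index=True, index_label="tile_id")
    return path


def read_tile_matrix(path: str | Path, manifest: pd.DataFrame):
    from .tiling import TileMatrix  # deferred: tiling imports io

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="tile_id")
    samples = list(manifest["sample_id"])
    tiles = df[["chrom", "start", "end", "n_cpg"]].copy()
    meth = df[[f"meth_{s}" for s in samples]]
    meth.columns = samples
    cov = df[[f"cov_{s}" for s in samples]]
    cov.columns = samples
    mc = df[[f"methreads_{s}" for s in samples]]
    mc.columns = samples
    tc = df[[f"totreads_{s}" for s in samples]]
    tc.columns = samples
    nc = df[[f"ncpg_{s}" for s in samples]]
    nc.columns = samples
    return TileMatrix(
        tiles=tiles,
        meth=meth,
        mean_cov=cov,
        meth_counts=mc,
        total_counts=tc,
        n_cpg=nc,
        manifest=manifest.reset_index(drop=True),
    )
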