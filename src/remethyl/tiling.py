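"""100 bp step-wise tiling of per-CpG methylation calls.

Tiles are non-overlapping windows aligned to multiples of the tile width.
The methylation of a tile in a sample is the unweighted mean of the
fractions of the CpGs covered in it; a tile is retained only if it passes
the CpG-count and coverage filters in every sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


class NoTilesError(ValueError):
    """No tile passes the filters in every sample."""


@dataclass
class TileMatrix:
    """Tiles x samples methylation matrix with replicate-group helpers.

    ``tiles`` is indexed by tile_id (``chrom:start-end``) with columns
    chrom/start/end/n_cpg (n_cpg = minimum across samples); ``meth``,
    ``mean_cov``, ``meth_counts``, ``total_counts`` and ``n_cpg`` are
    tile x sample frames.  Group (timepoint) means are arithmetic means of
    replicate values.
    """

    tiles: pd.DataFrame
    meth: pd.DataFrame
    mean_cov: pd.DataFrame
    meth_counts: pd.DataFrame
    total_counts: pd.DataFrame
    n_cpg: pd.DataFrame
    manifest: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.manifest["sample_id"])

    @property
    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for tp in self.manifest["timepoint"]:
            if tp not in seen:
                seen.append(tp)
        return seen

    def samples_for(self, timepoint: str) -> list[str]:
        sel = self.manifest.loc[self.manifest["timepoint"] == timepoint, "sample_id"]
        if sel.empty:
            raise KeyError(f"no samples for timepoint {timepoint!r}")
        return list(sel)

    def group_mean(self, timepoint: str) -> pd.Series:
        return self.meth[self.samples_for(timepoint)].mean(axis=1)

    def group_means(self) -> pd.DataFrame:
        return pd.DataFrame({tp: self.group_mean(tp) for tp in self.timepoints})

    def pooled_counts(self, timepoint: str) -> pd.DataFrame:
        """Replicate-pooled (meth, unmeth) read counts per tile."""
        cols = self.samples_for(timepoint)
        meth = self.meth_counts[cols].sum(axis=1)
        total = self.total_counts[cols].sum(axis=1)
        return pd.DataFrame({"meth": meth, "unmeth": total - meth})

    def __len__(self) -> int:
        return len(self.tiles)


def _per_sample_tiles(calls: pd.DataFrame, tile_width: int) -> pd.DataFrame:
    df = calls.loc[calls["coverage"] > 0, ["chrom", "pos", "coverage", "n_meth"]].copy()
    df["start"] = (df["pos"] // tile_width) * tile_width
    df["frac"] = df["n_meth"] / df["coverage"]
    g = df.groupby(["chrom", "start"], sort=True)
    out = g.agg(
        n_cpg=("pos", "size"),
        mean_cov=("coverage", "mean"),
        min_cov=("coverage", "min"),
        meth=("frac", "mean"),
        meth_reads=("n_meth", "sum"),
        total_reads=("coverage", "sum"),
    )
    return out


def make_tiles(
    calls: Mapping[str, pd.DataFrame],
    manifest: pd.DataFrame,
    tile_width: int = 100,
    min_cpg: int = 1,
    min_cov: float = 20.0,
    cov_rule: str = "tile_mean",
) -> TileMatrix:
    """Aggregate per-CpG calls into a filtered tile matrix.

    A tile is retained only if in *every* sample it has at least ``min_cpg``
    covered CpGs and passes the coverage rule: mean CpG coverage >= min_cov
    (``cov_rule="tile_mean"``, default) or every CpG >= min_cov
    (``cov_rule="each_cpg"``).
    """
    if cov_rule not in ("tile_mean", "each_cpg"):
        raise ValueError(f"unknown cov_rule {cov_rule!r}")
    samples = list(manifest["sample_id"])
    if not samples:
        raise ValueError("manifest lists no samples")
    missing = [s for s in samples if s not in calls]
    if missing:
        raise ValueError(f"missing call tables for samples {missing}")

    per_sample = {s: _per_sample_tiles(calls[s], tile_width) for s in samples}
    wide = pd.concat(per_sample, axis=1)  # columns: (sample, stat)

    ncpg = wide.xs("n_cpg", axis=1, level=1)
    covstat = wide.xs(
        "mean_cov" if cov_rule == "tile_mean" else "min_cov", axis=1, level=1
    )
    keep = (
        ncpg.notna().all(axis=1)
        & (ncpg >= min_cpg).all(axis=1)
        & (covstat >= min_cov).all(axis=1)
    )
    if not keep.any():
        raise NoTilesError("no tiles pass filters in every sample")
    wide = wide.loc[keep]

    index = pd.Index(
        [f"{c}:{s}-{s + tile_width}" for c, s in wide.index], name="tile_id"
    )
    tiles = pd.DataFrame(
        {
            "chrom": [c for c, _ in wide.index],
            "start": [s for _, s in wide.index],
            "end": [s + tile_width for _, s in wide.index],
            "n_cpg": wide.xs("n_cpg", axis=1, level=1).min(axis=1).astype(int).values,
        },
        index=index,
    )

    def stat(name: str) -> pd.DataFrame:
        out = wide.xs(name, axis=1, level=1).copy()
        out.index = index
        out.columns = list(out.columns)
        return out

    return TileMatrix(
        tiles=tiles,
        meth=stat("meth"),
        mean_cov=stat("mean_cov"),
        meth_counts=stat("meth_reads").astype(int),
        total_counts=stat("total_reads").astype(int),
        n_cpg=stat("n_cpg").astype(int),
        manifest=manifest.reset_index(drop=True),
    )


def sample_correlations(
    matrix: TileMatrix,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation between samples over tiles, plus an
    average-linkage clustering order on distance 1 - r.

    Zero-variance samples yield undefined correlations (NaN) with a warning,
    and clustering falls back to the manifest order.
    """
    if len(matrix) < 2:
        raise ValueError("sample correlations require >= 2 tiles")
    corr = matrix.meth.corr(method="pearson")
    if corr.isna().any().any():
        flat = matrix.meth.std(axis=0)
        degenerate = list(flat.index[flat == 0])
        warnings.warn(
            f"zero-variance samples {degenerate}: correlations undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return corr, list(corr.columns)
    dist = squareform(1.0 - corr.values, checks=False)
    order = hierarchy.leaves_list(hierarchy.linkage(dist, method="average"))
    return corr, [corr.columns[i] for i in order]


def tss_profile(
    matrix: TileMatrix,
    genes: pd.DataFrame,
    flank: int = 4000,
    bin_width: int = 200,
) -> pd.DataFrame:
    """Mean methylation by strand-oriented distance to the TSS, per group.

    ``genes`` needs columns chrom, tss, strand.  Every (tile, gene) pair with
    tile midpoint within ``flank`` of the TSS contributes to the bin its
    signed distance falls in (upstream negative).  Returns a frame indexed by
    bin left edge with one column per timepoint group.
    """
    if genes.empty:
        warnings.warn("no genes supplied: empty TSS profile", RuntimeWarning,
                      stacklevel=2)
        return pd.DataFrame(columns=matrix.timepoints)
    gm = matrix.group_means()
    mids = (matrix.tiles["start"] + matrix.tiles["end"]) // 2
    edges = np.arange(-flank, flank, bin_width)

    sums = {tp: np.zeros(len(edges)) for tp in gm.columns}
    counts = np.zeros(len(edges))
    for chrom, sub in matrix.tiles.groupby("chrom", sort=False):
        mid = mids.loc[sub.index].values
        order = np.argsort(mid)
        mid_sorted = mid[order]
        vals = gm.loc[sub.index].values[order]
        for _, gene in genes.loc[genes["chrom"] == chrom].iterrows():
            lo = np.searchsorted(mid_sorted, gene.tss - flank, side="left")
            hi = np.searchsorted(mid_sorted, gene.tss + flank, side="right")
            if lo == hi:
                continue
            d = mid_sorted[lo:hi] - gene.tss
            if gene.strand == "-":
                d = -d
            inside = (d >= -flank) & (d < flank)
            b = ((d[inside] + flank) // bin_width).astype(int)
            np.add.at(counts, b, 1)
            for j, tp in enumerate(gm.columns):
                np.add.at(sums[tp], b, vals[lo:hi][inside][:, j])
    with np.errstate(invalid="ignore"):
        prof = pd.DataFrame(
            {tp: sums[tp] / counts for tp in gm.columns},
            index=pd.Index(edges, name="dist_to_tss"),
        )
    return prof
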