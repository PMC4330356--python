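"""Trajectory patterns across control -> d0 -> d21, candidate ranking, and
consecutive-region merging.

The four loss/recovery patterns observed for single-copy loci after transient
loss of maintenance methylation:

* P1 — full demethylation, full remethylation (near-zero at d0, back to
  original levels by d21);
* P2 — partial demethylation (20–75% at d0), full remethylation;
* P3 — complete loss with no recovery (the imprinted-gDMD behaviour);
* P4 — loss with incomplete recovery (the gDMD-like signature).

STABLE and HYPER cover unchanged and gaining trajectories; anything else is
UNCLASSIFIED.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PATTERNS = ("P1", "P2", "P3", "P4", "STABLE", "HYPER", "UNCLASSIFIED")


@dataclass(frozen=True)
class TrajectoryCall:
    m_control: float
    m_d0: float
    m_d21: float
    pattern: str


def classify_trajectory(
    m_control: float,
    m_d0: float,
    m_d21: float,
    low: float = 0.20,
    partial_hi: float = 0.75,
    recover_tol: float = 0.20,
) -> str:
    """Assign one trajectory pattern to a (control, d0, d21) triple.

    Rules, in order: a gain of >= 0.20 at d21 -> HYPER; no quantifiable loss
    at d0 with d21 within tolerance of control -> STABLE; otherwise loss
    occurred, ``recovered`` means control - d21 < recover_tol, and the triple
    is P1 (d0 < low, recovered), P2 (low <= d0 <= partial_hi, recovered),
    P3 (d0 < low and d21 < low: no recovery), P4 (not recovered, not P3),
    or UNCLASSIFIED.  Total: every triple in [0,1]^3 gets exactly one label.
    """
    for v in (m_control, m_d0, m_d21):
        if not 0.0 <= v <= 1.0:
            raise ValueError("methylation fractions must lie in [0, 1]")
    if m_d21 >= m_control + 0.20:
        return "HYPER"
    if (m_control - m_d0 < recover_tol) and (m_d21 >= m_control - recover_tol):
        return "STABLE"
    recovered = (m_control - m_d21) < recover_tol
    if recovered and m_d0 < low:
        return "P1"
    if recovered and low <= m_d0 <= partial_hi:
        return "P2"
    if m_d0 < low and m_d21 < low:
        return "P3"
    if not recovered:
        return "P4"
    return "UNCLASSIFIED"


def classify_table(
    means: pd.DataFrame,
    control: str = "control",
    d0: str = "d0",
    d21: str = "d21",
    low: float = 0.20,
    partial_hi: float = 0.75,
    recover_tol: float = 0.20,
) -> pd.DataFrame:
    """Vectorised :func:`classify_trajectory` over a group-means frame."""
    mc = means[control].values
    m0 = means[d0].values
    m21 = means[d21].values
    hyper = m21 >= mc + 0.20
    stable = ~hyper & (mc - m0 < recover_tol) & (m21 >= mc - recover_tol)
    rest = ~stable & ~hyper
    recovered = (mc - m21) < recover_tol
    p1 = rest & recovered & (m0 < low)
    p2 = rest & recovered & (m0 >= low) & (m0 <= partial_hi)
    p3 = rest & ~p1 & ~p2 & (m0 < low) & (m21 < low)
    p4 = rest & ~p1 & ~p2 & ~p3 & ~recovered
    pattern = np.select(
        [stable, hyper, p1, p2, p3, p4],
        ["STABLE", "HYPER", "P1", "P2", "P3", "P4"],
        default="UNCLASSIFIED",
    )
    return pd.DataFrame(
        {
            "m_control": mc,
            "m_d0": m0,
            "m_d21": m21,
            "pattern": pattern,
        },
        index=means.index,
    )


DEFAULT_BIN_EDGES = (85.0, 70.0, 50.0, 20.0, 0.0)


def loss_bin(loss_pct: float, edges: Sequence[float] = DEFAULT_BIN_EDGES) -> str:
    """Label the loss bin: top bin is [85,100], lower bins half-open."""
    if loss_pct >= edges[0]:
        return f"[{edges[0]:g},100]"
    for hi, lo in zip(edges[:-1], edges[1:]):
        if lo <= loss_pct < hi:
            return f"[{lo:g},{hi:g})"
    return f"<{edges[-1]:g}"


def rank_candidates(
    tile_table: pd.DataFrame,
    imprinted: Iterable[str] = (),
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Rank genes by mean fractional methylation loss at d21.

    ``tile_table`` needs columns gene_id, m_control, m_d21 (one row per
    annotated tile, typically the hypomethylated tiles of the control-vs-d21
    comparison).  Per tile, loss% = 100 * (m_control - m_d21) / m_control;
    per gene, the average of its tiles' loss percentages ("average of
    methylation averages of tiles associated to unique gene IDs").  Genes
    whose tiles all have zero control methylation are excluded.
    """
    df = tile_table.dropna(subset=["gene_id"]).copy()
    usable = df["m_control"] > 0
    excluded = set(df.loc[~usable, "gene_id"]) - set(df.loc[usable, "gene_id"])
    if excluded:
        warnings.warn(
            f"{len(excluded)} genes excluded from ranking: all tiles have "
            "zero control methylation",
            RuntimeWarning,
            stacklevel=2,
        )
    df = df[usable]
    df["loss_pct"] = 100.0 * (df["m_control"] - df["m_d21"]) / df["m_control"]
    imprinted = set(imprinted)
    grouped = (
        df.groupby("gene_id")
        .agg(n_tiles=("loss_pct", "size"), loss_pct=("loss_pct", "mean"))
        .reset_index()
    )
    grouped["bin"] = [loss_bin(l, bin_edges) for l in grouped["loss_pct"]]
    grouped["imprinted_flag"] = grouped["gene_id"].isin(imprinted)
    return grouped.sort_values(
        ["loss_pct", "gene_id"], ascending=[False, True], ignore_index=True
    )


def merge_tiles(tiles: pd.DataFrame, max_gap: int = 500) -> pd.DataFrame:
    """Merge tiles into consecutive regions separated by at most ``max_gap``
    bp (inclusive).  Single linear pass per chromosome; idempotent and
    independent of input row order.

    ``tiles`` needs columns chrom, start, end; the index supplies member tile
    ids.  Returns regions with columns chrom, start, end, n_tiles, tile_ids.
    """
    if tiles.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_tiles", "tile_ids"])
    df = tiles.sort_values(["chrom", "start", "end"])
    regions = []
    cur = None
    for tile_id, row in df.iterrows():
        if (
            cur is not None
            and row["chrom"] == cur["chrom"]
            and row["start"] - cur["end"] <= max_gap
        ):
            cur["end"] = max(cur["end"], row["end"])
            cur["tile_ids"].append(tile_id)
        else:
            if cur is not None:
                regions.append(cur)
            cur = {
                "chrom": row["chrom"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "tile_ids": [tile_id],
            }
    regions.append(cur)
    out = pd.DataFrame(
        [
            (r["chrom"], r["start"], r["end"], len(r["tile_ids"]), r["tile_ids"])
            for r in regions
        ],
        columns=["chrom", "start", "end", "n_tiles", "tile_ids"],
    )
    return out
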