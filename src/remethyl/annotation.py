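"""Genomic-context annotation of tiles and composition statistics.

Each tile receives exactly one genomic feature by an any-overlap test with a
fixed priority (promoter-TSS > TTS > 5UTR > 3UTR > exon > intron > noncoding
> intergenic), a CpG-island flag (any overlap), and repeat context (class of
the overlapping repeat, distance to the nearest repeat, within-1-kb flag).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

FEATURE_PRIORITY = (
    "promoter-TSS",
    "TTS",
    "5UTR",
    "3UTR",
    "exon",
    "intron",
    "noncoding",
)


def _trees(intervals: pd.DataFrame, payload_cols: Sequence[str]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        tree = IntervalTree()
        for row in sub.itertuples(index=False):
            tree.addi(row.start, row.end, tuple(getattr(row, c) for c in payload_cols))
        trees[chrom] = tree
    return trees


def assign_features(
    tiles: pd.DataFrame,
    feature_intervals: pd.DataFrame,
    priority: Sequence[str] = FEATURE_PRIORITY,
) -> pd.DataFrame:
    """Assign one feature label and gene_id per tile.

    ``tiles`` needs chrom/start/end (index = tile ids); ``feature_intervals``
    needs chrom/start/end/gene_id/feature.  Overlap ties are broken by the
    priority order, then by longest overlap.  Tiles overlapping nothing are
    ``intergenic`` with no gene.
    """
    rank = {f: i for i, f in enumerate(priority)}
    unknown = set(feature_intervals["feature"]) - set(priority)
    if unknown:
        raise ValueError(f"feature intervals carry unknown labels {sorted(unknown)}")
    trees = _trees(feature_intervals, ["feature", "gene_id"])
    features = []
    gene_ids = []
    for row in tiles.itertuples():
        hits = trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end)
        if not hits:
            features.append("intergenic")
            gene_ids.append(None)
            continue
        best = min(
            hits,
            key=lambda iv: (
                rank[iv.data[0]],
                -(min(iv.end, row.end) - max(iv.begin, row.start)),
                iv.begin,
            ),
        )
        features.append(best.data[0])
        gene_ids.append(best.data[1])
    return pd.DataFrame({"feature": features, "gene_id": gene_ids}, index=tiles.index)


def cgi_overlap(tiles: pd.DataFrame, cgis: pd.DataFrame) -> pd.Series:
    """CpG-island membership: any overlap of >= 1 bp."""
    trees = _trees(cgis, ["name"]) if not cgis.empty else {}
    flags = [
        bool(trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end))
        for row in tiles.itertuples()
    ]
    return pd.Series(flags, index=tiles.index, name="cgi")


def repeat_context(
    tiles: pd.DataFrame,
    repeats: pd.DataFrame,
    proximity: int = 1000,
) -> pd.DataFrame:
    """Repeat overlap class, distance to the nearest repeat, and a
    within-``proximity`` flag for each tile.

    Distance is 0 iff the tile overlaps a repeat; otherwise the smallest gap
    to any repeat on the chromosome (``inf`` if the chromosome has none).
    When a tile overlaps repeats of several classes the class with the
    longest overlap wins.
    """
    if repeats.empty:
        return pd.DataFrame(
            {
                "repeat_overlap": [None] * len(tiles),
                "distance_to_repeat": np.inf,
                "repeat_within": False,
            },
            index=tiles.index,
        )
    trees = _trees(repeats, ["repeat_class"])
    bounds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in repeats.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        bounds[chrom] = (s["start"].values, np.sort(s["end"].values))

    classes: list[str | None] = []
    dists: list[float] = []
    for row in tiles.itertuples():
        hits = trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end)
        if hits:
            best = max(
                hits,
                key=lambda iv: (min(iv.end, row.end) - max(iv.begin, row.start), -iv.begin),
            )
            classes.append(best.data[0])
            dists.append(0.0)
            continue
        classes.append(None)
        if row.chrom not in bounds:
            dists.append(np.inf)
            continue
        starts, ends = bounds[row.chrom]
        right = np.searchsorted(starts, row.end, side="left")
        d_right = starts[right] - row.end if right < len(starts) else np.inf
        left = np.searchsorted(ends, row.start, side="right") - 1
        d_left = row.start - ends[left] if left >= 0 else np.inf
        dists.append(float(min(d_right, d_left)))
    out = pd.DataFrame(
        {"repeat_overlap": classes, "distance_to_repeat": dists}, index=tiles.index
    )
    out["repeat_within"] = out["distance_to_repeat"] <= proximity
    return out


def composition_chi2(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) comparing two class
    compositions.  Classes with zero combined count are pooled out with a
    warning.  Returns (chi2, dof, p)."""
    classes = sorted(set(counts_a) | set(counts_b))
    if len(classes) < 2:
        raise ValueError("chi-square needs >= 2 classes")
    table = np.array(
        [
            [counts_a.get(c, 0) for c in classes],
            [counts_b.get(c, 0) for c in classes],
        ],
        dtype=float,
    )
    empty = table.sum(axis=0) == 0
    if empty.any():
        warnings.warn(
            f"classes with zero total pooled out: "
            f"{[c for c, e in zip(classes, empty) if e]}",
            RuntimeWarning,
            stacklevel=2,
        )
        table = table[:, ~empty]
        if table.shape[1] < 2:
            raise ValueError("fewer than 2 non-empty classes")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("a group has zero total count")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> float:
    """Two-sided rank-sum p-value.

    Exact null enumeration when both groups have <= ``exact_max_n``
    observations and there are no cross-ties; normal approximation
    otherwise.  Completely tied data gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need >= 1 value")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = (
        "exact"
        if (len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def feature_shift_test(
    values_control: Mapping[str, Sequence[float]],
    values_d21: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Per-feature-class Wilcoxon rank-sum between control and d21 tile
    methylation, with BH-adjusted q-values across classes."""
    classes = sorted(set(values_control) & set(values_d21))
    rows = []
    for c in classes:
        a, b = values_control[c], values_d21[c]
        if len(a) == 0 or len(b) == 0:
            continue
        rows.append((c, len(a), len(b), wilcoxon_rank_sum(a, b)))
    out = pd.DataFrame(rows, columns=["feature", "n_control", "n_d21", "p_value"])
    if not out.empty:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.set_index("feature")
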