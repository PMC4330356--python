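"""Per-tile two-group differential methylation and methylation-state calls.

Two significance recipes are provided:

* ``ttest`` — Welch two-sample t-test on replicate tile fractions with
  P < alpha and an absolute mean difference >= 20 percentage points.
* ``counts`` — two-sided Fisher's exact test on the replicate-pooled
  (methylated, unmethylated) read counts, Benjamini–Hochberg corrected
  across all tested tiles at q < 0.01, again with the >= 20-point
  effect-size gate.

The effect-size gate is mandatory in both recipes: a tiny P-value with a
difference below 20 points is still called stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tiling import TileMatrix

HIGH, INTERMEDIATE, LOW = "HIGH", "INTERMEDIATE", "LOW"


@dataclass(frozen=True)
class DifferentialResult:
    mean_a: float
    mean_b: float
    diff: float
    p_value: float
    q_value: float | None
    status: str  # hypo | hyper | stable
    flagged: bool = False  # zero within-group variance with unequal means


def _status(diff: float, significant: bool, min_diff: float) -> str:
    if significant and diff <= -min_diff:
        return "hypo"
    if significant and diff >= min_diff:
        return "hyper"
    return "stable"


def test_tile_ttest(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    alpha: float = 0.05,
    min_diff: float = 0.20,
) -> DifferentialResult:
    """Welch t-test on one tile's replicate fractions (group B vs group A)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test requires >= 2 replicates per group")
    diff = float(b.mean() - a.mean())
    flagged = False
    if a.var(ddof=1) <= 1e-14 and b.var(ddof=1) <= 1e-14:
        if diff == 0.0:
            p = 1.0
            significant = False
        else:
            # degenerate: no within-group variance but distinct means
            flagged = True
            p = float("nan")
            significant = abs(diff) >= min_diff
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        significant = (p < alpha) and (abs(diff) >= min_diff)
    return DifferentialResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        diff=diff,
        p_value=p,
        q_value=None,
        status=_status(diff, significant, min_diff),
        flagged=flagged,
    )


def test_tile_counts(
    counts_a: tuple[int, int],
    counts_b: tuple[int, int],
    q_threshold: float = 0.01,
    min_diff: float = 0.20,
) -> DifferentialResult:
    """Fisher's exact test on one tile's pooled (meth, unmeth) counts.

    For a single tile the BH-adjusted q equals the raw p; q-values over a
    collection of tiles come from :func:`differential_table`.
    """
    ma, ua = counts_a
    mb, ub = counts_b
    if min(ma, ua, mb, ub) < 0:
        raise ValueError("counts must be >= 0")
    if ma + ua == 0 or mb + ub == 0:
        raise ValueError("zero total reads in a group")
    p = float(stats.fisher_exact([[ma, ua], [mb, ub]], alternative="two-sided")[1])
    mean_a = ma / (ma + ua)
    mean_b = mb / (mb + ub)
    diff = mean_b - mean_a
    significant = (p < q_threshold) and (abs(diff) >= min_diff)
    return DifferentialResult(
        mean_a=mean_a,
        mean_b=mean_b,
        diff=diff,
        p_value=p,
        q_value=p,
        status=_status(diff, significant, min_diff),
    )


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg q-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    matrix: TileMatrix,
    group_a: str,
    group_b: str,
    method: str = "counts",
    alpha: float = 0.05,
    q_threshold: float = 0.01,
    min_diff: float = 0.20,
) -> pd.DataFrame:
    """Two-group comparison of every tile in a matrix.

    Returns a frame indexed by tile_id with mean_a, mean_b, diff, p_value,
    q_value and status.  ``counts`` pools replicate reads per group and
    applies Fisher + BH at ``q_threshold``; ``ttest`` applies Welch + raw
    ``alpha``.  Tiles with zero pooled reads in a group are skipped with a
    warning under the counts method.
    """
    ma = matrix.group_mean(group_a)
    mb = matrix.group_mean(group_b)
    out = pd.DataFrame(
        {"mean_a": ma, "mean_b": mb, "diff": mb - ma}, index=matrix.tiles.index
    )
    if method == "ttest":
        a = matrix.meth[matrix.samples_for(group_a)].values
        b = matrix.meth[matrix.samples_for(group_b)].values
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        var0 = (a.var(axis=1, ddof=1) <= 1e-14) & (b.var(axis=1, ddof=1) <= 1e-14)
        equal = var0 & (out["diff"].values == 0)
        distinct = var0 & ~equal
        p[equal] = 1.0
        p[distinct] = np.nan
        significant = (p < alpha) & (out["diff"].abs().values >= min_diff)
        significant[distinct] = np.abs(out["diff"].values[distinct]) >= min_diff
        out["p_value"] = p
        out["q_value"] = np.nan
        out["flagged"] = distinct
    elif method == "counts":
        ca = matrix.pooled_counts(group_a)
        cb = matrix.pooled_counts(group_b)
        tot_a = ca.sum(axis=1)
        tot_b = cb.sum(axis=1)
        testable = (tot_a > 0) & (tot_b > 0)
        if (~testable).any():
            warnings.warn(
                f"{int((~testable).sum())} tiles skipped: zero pooled reads "
                f"in a group",
                RuntimeWarning,
                stacklevel=2,
            )
        # pooled-count fractions are what the exact test compares
        out["mean_a"] = ca["meth"] / tot_a
        out["mean_b"] = cb["meth"] / tot_b
        out["diff"] = out["mean_b"] - out["mean_a"]
        p = np.full(len(out), np.nan)
        idx = np.where(testable.values)[0]
        a_meth = ca["meth"].values
        a_un = ca["unmeth"].values
        b_meth = cb["meth"].values
        b_un = cb["unmeth"].values
        for i in idx:
            p[i] = stats.fisher_exact(
                [[a_meth[i], a_un[i]], [b_meth[i], b_un[i]]]
            )[1]
        q = np.full(len(out), np.nan)
        q[idx] = bh_adjust(p[idx])
        out["p_value"] = p
        out["q_value"] = q
        significant = (q < q_threshold) & (out["diff"].abs().values >= min_diff)
        out["flagged"] = False
    else:
        raise ValueError(f"unknown method {method!r}")

    out["status"] = np.select(
        [
            significant & (out["diff"].values <= -min_diff),
            significant & (out["diff"].values >= min_diff),
        ],
        ["hypo", "hyper"],
        default="stable",
    )
    return out


def classify_state(values: pd.Series | np.ndarray) -> np.ndarray:
    """HIGH (>0.80) / INTERMEDIATE ([0.20, 0.80]) / LOW (<0.20) per value."""
    v = np.asarray(values, dtype=float)
    return np.select([v > 0.80, v < 0.20], [HIGH, LOW], default=INTERMEDIATE)


def state_fractions(matrix: TileMatrix, group: str) -> dict[str, float]:
    """Fraction of tiles in each methylation state for a replicate group."""
    states = classify_state(matrix.group_mean(group))
    n = len(states)
    return {
        HIGH: float((states == HIGH).sum()) / n,
        INTERMEDIATE: float((states == INTERMEDIATE).sum()) / n,
        LOW: float((states == LOW).sum()) / n,
    }


def retention_calls(
    matrix: TileMatrix,
    control: str = "control",
    d0: str = "d0",
    min_loss: float = 0.20,
) -> pd.DataFrame:
    """Methylation retention at d0 for tiles that lost >= ``min_loss``
    absolute methylation from control.

    ``retained_frac`` is m_d0 / m_control (fraction of original levels);
    classes: ``retained>40%`` if retained_frac > 0.40, else ``retained>20%``
    if > 0.20, else ``not_retained``; ``retained>40%`` tiles are a subset of
    the >20% set (both boolean columns are emitted).  ``retained_abs_40_74``
    flags absolute d0 methylation in [0.40, 0.74].  Tiles with zero control
    methylation are excluded (undefined fraction) with a warning.
    """
    mc = matrix.group_mean(control)
    m0 = matrix.group_mean(d0)
    defined = mc > 0
    if (~defined).any():
        warnings.warn(
            f"{int((~defined).sum())} tiles excluded from retention: "
            "control methylation is zero",
            RuntimeWarning,
            stacklevel=2,
        )
    out = pd.DataFrame({"m_control": mc[defined], "m_d0": m0[defined]})
    out["lost"] = (out["m_control"] - out["m_d0"]) >= min_loss
    out["retained_frac"] = out["m_d0"] / out["m_control"]
    out["retained_abs"] = out["m_d0"]
    out["retained_gt20"] = out["lost"] & (out["retained_frac"] > 0.20)
    out["retained_gt40"] = out["lost"] & (out["retained_frac"] > 0.40)
    out["retention_class"] = np.select(
        [out["retained_gt40"], out["retained_gt20"]],
        ["retained>40%", "retained>20%"],
        default="not_retained",
    )
    out.loc[~out["lost"], "retention_class"] = "not_lost"
    out["retained_abs_40_74"] = (
        out["lost"] & (out["m_d0"] >= 0.40) & (out["m_d0"] <= 0.74)
    )
    return out
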