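import math

import numpy as np
import pandas as pd
import pytest

from remethyl.differential import (
    bh_adjust,
    classify_state,
    differential_table,
    retention_calls,
    state_fractions,
)
from remethyl.differential import test_tile_counts as fisher_tile_test
from remethyl.differential import test_tile_ttest as welch_tile_test


# ---------------------------------------------------------------- oracles


def welch_oracle(a, b):
    """Textbook Welch t statistic and two-sided p via the t distribution."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a), np.asarray(b)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * tdist.sf(abs(t), df)


def fisher_oracle(table):
    """Two-sided Fisher p by full enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def bh_oracle_rejections(pvals, q):
    """Hand BH step-up: largest k with p_(k) <= k*q/m."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * q / m:
            k_max = rank
    return set(order[:k_max])


# ------------------------------------------------------------------ t-test


def test_ttest_identical_groups_stable():
    r = welch_tile_test([0.8, 0.8, 0.8], [0.8, 0.8, 0.8])
    assert r.diff == 0.0
    assert r.p_value == 1.0
    assert r.status == "stable"


def test_ttest_clear_loss_is_hypo_and_matches_welch_oracle():
    a, b = [0.9, 0.88, 0.92], [0.15, 0.1, 0.2]
    r = welch_tile_test(a, b)
    assert r.status == "hypo"
    assert r.p_value == pytest.approx(welch_oracle(a, b))


def test_effect_size_gate_is_mandatory():
    # |diff| = 0.19 with minuscule p is still stable
    a = [0.500, 0.501, 0.499, 0.500]
    b = [0.690, 0.691, 0.689, 0.690]
    r = welch_tile_test(a, b)
    assert abs(r.diff) == pytest.approx(0.19, abs=1e-9)
    assert r.p_value < 1e-6
    assert r.status == "stable"


def test_ttest_zero_variance_distinct_means_flagged():
    r = welch_tile_test([0.9, 0.9, 0.9], [0.1, 0.1, 0.1])
    assert r.flagged
    assert r.status == "hypo"


# ------------------------------------------------------------------ counts


def test_counts_identical_tables_stable():
    r = fisher_tile_test((50, 50), (50, 50))
    assert r.p_value == pytest.approx(1.0)
    assert r.status == "stable"


def test_counts_p_equals_hypergeometric_enumeration():
    r = fisher_tile_test((90, 10), (50, 50))
    assert r.p_value == pytest.approx(fisher_oracle([[90, 10], [50, 50]]))
    assert r.status == "hypo"  # fraction fell 0.9 -> 0.5


def test_counts_zero_total_rejected():
    with pytest.raises(ValueError, match="zero total"):
        fisher_tile_test((0, 0), (5, 5))


@pytest.mark.parametrize("tot_a,tot_b", [(10, 10), (25, 30), (60, 60), (7, 41)])
def test_fisher_matches_enumeration_over_table_grid(tot_a, tot_b):
    # dual route: scipy's exact test vs independent full-margin enumeration
    for ma in range(0, tot_a + 1, max(1, tot_a // 5)):
        for mb in range(0, tot_b + 1, max(1, tot_b // 5)):
            table = [[ma, tot_a - ma], [mb, tot_b - mb]]
            r = fisher_tile_test((ma, tot_a - ma), (mb, tot_b - mb))
            assert r.p_value == pytest.approx(fisher_oracle(table), rel=1e-9)


# ---------------------------------------------------------------------- BH


def test_bh_hand_rule_on_fixed_vector():
    p = np.array([0.001, 0.002, 0.03, 0.8])
    q = bh_adjust(p)
    rejected = set(np.where(q < 0.01)[0])
    assert rejected == {0, 1}
    assert rejected == bh_oracle_rejections(p, 0.01)


def test_bh_rejections_invariant_under_permutation_and_monotone():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=40) ** 3
    q = bh_adjust(p)
    # q monotone in p
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    for _ in range(5):
        perm = rng.permutation(len(p))
        qp = bh_adjust(p[perm])
        assert {i for i in range(len(p)) if q[i] < 0.05} == {
            perm[j] for j in range(len(p)) if qp[j] < 0.05
        }
        assert bh_oracle_rejections(p, 0.05) == set(np.where(q < 0.05)[0])


# ------------------------------------------------------------ matrix level


def test_status_counts_conserved(small_pipeline):
    for table in (small_pipeline.diff_d0, small_pipeline.diff_d21):
        counts = table["status"].value_counts()
        assert counts.sum() == len(small_pipeline.matrix)


def test_ttest_and_counts_tables_agree_on_strong_effects(small_pipeline):
    m = small_pipeline.matrix
    t_tab = differential_table(m, "control", "d21", method="ttest")
    c_tab = small_pipeline.diff_d21
    strong = c_tab[(c_tab["diff"].abs() > 0.4) & (c_tab["status"] == "hypo")].index
    agree = (t_tab.loc[strong, "status"] == "hypo").mean()
    assert agree >= 0.9


# ------------------------------------------------------------------ states


def test_state_partition_boundaries():
    states = classify_state([0.95, 0.85, 0.80, 0.5, 0.20, 0.1])
    assert list(states) == [
        "HIGH", "HIGH", "INTERMEDIATE", "INTERMEDIATE", "INTERMEDIATE", "LOW",
    ]


def test_state_fractions_sum_to_one(small_pipeline):
    for tp in ("control", "d0", "d21"):
        fr = state_fractions(small_pipeline.matrix, tp)
        assert sum(fr.values()) == pytest.approx(1.0)


# --------------------------------------------------------------- retention


def _matrix_with_means(pairs):
    """Tiny two-sample matrix with given (control, d0) tile means."""
    from remethyl.tiling import make_tiles

    rows_c, rows_d = [], []
    for i, (mc, md) in enumerate(pairs):
        pos = i * 100 + 10
        rows_c.append(("chr1", pos, "+", 100, int(round(mc * 100))))
        rows_d.append(("chr1", pos, "+", 100, int(round(md * 100))))
    calls = {
        "c1": pd.DataFrame(rows_c, columns=["chrom", "pos", "strand", "coverage", "n_meth"]),
        "d1": pd.DataFrame(rows_d, columns=["chrom", "pos", "strand", "coverage", "n_meth"]),
    }
    manifest = pd.DataFrame(
        {"sample_id": ["c1", "d1"], "timepoint": ["control", "d0"], "replicate": [1, 1]}
    )
    return make_tiles(calls, manifest)


def test_retention_two_stage_rule():
    m = _matrix_with_means([(0.9, 0.5), (0.9, 0.85), (0.9, 0.05), (0.9, 0.25)])
    r = retention_calls(m)
    assert list(r["retention_class"]) == [
        "retained>40%",  # lost 0.4, retained 0.556 of original
        "not_lost",      # delta < 0.20
        "not_retained",  # retained 0.056
        "retained>20%",  # retained 0.278
    ]
    # >40% is a subset of >20%
    assert (r["retained_gt40"] <= r["retained_gt20"]).all()
    assert r["retained_frac"].iloc[0] == pytest.approx(0.5 / 0.9)


def test_retention_absolute_band_flag():
    m = _matrix_with_means([(0.95, 0.60), (0.95, 0.30)])
    r = retention_calls(m)
    assert list(r["retained_abs_40_74"]) == [True, False]


def test_retention_zero_control_excluded_with_warning():
    m = _matrix_with_means([(0.0, 0.0), (0.9, 0.4)])
    with pytest.warns(RuntimeWarning, match="control methylation is zero"):
        r = retention_calls(m)
    assert len(r) == 1
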