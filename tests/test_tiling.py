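import numpy as np
import pandas as pd
import pytest

from remethyl.tiling import NoTilesError, make_tiles, sample_correlations, tss_profile


def _calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "coverage", "n_meth"])


def _manifest(samples):
    return pd.DataFrame(
        {
            "sample_id": [s for s, _ in samples],
            "timepoint": [t for _, t in samples],
            "replicate": [1] * len(samples),
        }
    )


def test_tile_methylation_is_unweighted_cpg_mean():
    calls = {
        "s1": _calls(
            [
                ("chr1", 10, "+", 100, 80),  # 0.8
                ("chr1", 40, "+", 50, 30),  # 0.6
                ("chr1", 90, "+", 20, 8),  # 0.4
            ]
        )
    }
    m = make_tiles(calls, _manifest([("s1", "control")]))
    assert len(m) == 1
    assert m.meth.iloc[0, 0] == pytest.approx(0.6)
    assert m.tiles["n_cpg"].iloc[0] == 3


def test_low_coverage_in_one_sample_drops_tile_everywhere():
    good = _calls([("chr1", 10, "+", 30, 10), ("chr1", 150, "+", 30, 10)])
    poor = _calls([("chr1", 10, "+", 19, 5), ("chr1", 150, "+", 30, 10)])
    calls = {"a": good, "b": poor}
    m = make_tiles(calls, _manifest([("a", "control"), ("b", "d0")]))
    # tile [0,100) has mean coverage 19 in sample b: dropped for both samples
    assert list(m.tiles["start"]) == [100]


def test_tile_missing_in_one_sample_dropped():
    calls = {
        "a": _calls([("chr1", 10, "+", 30, 10), ("chr1", 150, "+", 30, 10)]),
        "b": _calls([("chr1", 150, "+", 30, 10)]),
    }
    m = make_tiles(calls, _manifest([("a", "control"), ("b", "d0")]))
    assert list(m.tiles["start"]) == [100]


def test_no_tiles_passing_raises():
    calls = {"a": _calls([("chr1", 10, "+", 5, 1)])}
    with pytest.raises(NoTilesError):
        make_tiles(calls, _manifest([("a", "control")]), min_cov=20)


def test_filters_monotone_in_min_cov():
    rng = np.random.default_rng(0)
    rows = [
        ("chr1", int(p), "+", int(c), int(c * 0.4))
        for p, c in zip(
            rng.choice(5000, size=300, replace=False), rng.integers(5, 60, 300)
        )
    ]
    calls = {"a": _calls(rows)}
    man = _manifest([("a", "control")])
    sizes = []
    for min_cov in (5, 15, 25, 35):
        try:
            sizes.append(len(make_tiles(calls, man, min_cov=min_cov)))
        except NoTilesError:
            sizes.append(0)
    assert sizes == sorted(sizes, reverse=True)


def test_tile_aggregation_matches_bruteforce():
    # oracle: direct per-tile recomputation with plain dict arithmetic
    rng = np.random.default_rng(42)
    for trial in range(50):
        n = rng.integers(5, 40)
        pos = rng.choice(2000, size=n, replace=False)
        cov = rng.integers(1, 50, size=n)
        meth = rng.binomial(cov, 0.5)
        calls = {"s": _calls([("c", int(p), "+", int(c), int(m))
                              for p, c, m in zip(pos, cov, meth)])}
        width = int(rng.choice([50, 100, 250]))
        min_cov = float(rng.choice([1, 10, 20]))
        expected = {}
        for p, c, m in zip(pos, cov, meth):
            expected.setdefault(p // width * width, []).append((c, m))
        kept = {
            t: vals
            for t, vals in expected.items()
            if np.mean([c for c, _ in vals]) >= min_cov
        }
        try:
            mtx = make_tiles(calls, _manifest([("s", "control")]),
                             tile_width=width, min_cov=min_cov)
            got = dict(zip(mtx.tiles["start"], mtx.meth["s"]))
        except NoTilesError:
            got = {}
        assert set(got) == set(kept)
        for t, vals in kept.items():
            frac = np.mean([m / c for c, m in vals])
            assert got[t] == pytest.approx(frac)


def test_duplicated_sample_correlates_perfectly():
    base = _calls([("chr1", int(p), "+", 30, int(m)) for p, m in
                   zip(range(0, 1000, 100), [3, 9, 15, 21, 27, 3, 9, 15, 21, 27])])
    calls = {"a": base, "b": base.copy()}
    m = make_tiles(calls, _manifest([("a", "control"), ("b", "control")]))
    corr, _ = sample_correlations(m)
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert np.allclose(np.diag(corr.values), 1.0)
    assert np.allclose(corr.values, corr.values.T)


def test_exact_anticorrelation():
    a = _calls([("chr1", 10, "+", 10, 0), ("chr1", 110, "+", 10, 5), ("chr1", 210, "+", 10, 10)])
    b = _calls([("chr1", 10, "+", 10, 10), ("chr1", 110, "+", 10, 5), ("chr1", 210, "+", 10, 0)])
    m = make_tiles(calls={"a": a, "b": b},
                   manifest=_manifest([("a", "control"), ("b", "d0")]), min_cov=1)
    corr, _ = sample_correlations(m)
    assert corr.loc["a", "b"] == pytest.approx(-1.0)


def test_pearson_matches_direct_formula():
    x = np.array([0.1, 0.4, 0.6, 0.9])
    y = np.array([0.2, 0.3, 0.7, 0.8])
    # textbook Pearson as the oracle
    r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    a = _calls([("chr1", int(i * 100 + 10), "+", 10, int(round(v * 10)))
                for i, v in enumerate(x)])
    b = _calls([("chr1", int(i * 100 + 10), "+", 10, int(round(v * 10)))
                for i, v in enumerate(y)])
    m = make_tiles({"a": a, "b": b},
                   _manifest([("a", "control"), ("b", "d0")]), min_cov=1)
    corr, _ = sample_correlations(m)
    assert corr.loc["a", "b"] == pytest.approx(r_oracle)


def test_zero_variance_sample_warns_and_reports_missing():
    a = _calls([("chr1", 10, "+", 10, 5), ("chr1", 110, "+", 10, 5)])
    b = _calls([("chr1", 10, "+", 10, 2), ("chr1", 110, "+", 10, 9)])
    m = make_tiles({"a": a, "b": b},
                   _manifest([("a", "control"), ("b", "d0")]), min_cov=1)
    with pytest.warns(RuntimeWarning, match="zero-variance"):
        corr, order = sample_correlations(m)
    assert np.isnan(corr.loc["a", "b"])
    assert order == ["a", "b"]


def _uniform_matrix(frac, genes_positions, chrom_len=40_000):
    n_meth = int(round(frac * 20))
    rows = [("chr1", p, "+", 20, n_meth) for p in range(50, chrom_len, 100)]
    calls = {"s": _calls(rows)}
    return make_tiles(calls, _manifest([("s", "control")]))


def test_tss_profile_flat_for_uniform_methylation():
    m = _uniform_matrix(0.7, None)
    genes = pd.DataFrame({"chrom": ["chr1"], "tss": [20_000], "strand": ["+"]})
    prof = tss_profile(m, genes)
    assert np.allclose(prof["control"].dropna(), 0.7)


def test_tss_profile_dip_and_strand_orientation():
    # step input: 0 within 1 kb of the TSS, 0.8 elsewhere; oracle = binning
    tss = 20_000
    rows = []
    for p in range(50, 40_000, 100):
        frac = 0.0 if abs(p - tss) <= 1000 else 0.8
        rows.append(("chr1", p, "+", 20, int(frac * 20)))
    m = make_tiles({"s": _calls(rows)}, _manifest([("s", "control")]))
    genes = pd.DataFrame({"chrom": ["chr1"], "tss": [tss], "strand": ["-"]})
    prof = tss_profile(m, genes, flank=4000, bin_width=200)
    center = prof.loc[0, "control"]
    edge = prof.loc[-4000, "control"]
    assert center == pytest.approx(0.0)
    assert edge == pytest.approx(0.8)
    # dip symmetric under strand flip
    genes_plus = genes.assign(strand="+")
    prof_plus = tss_profile(m, genes_plus, flank=4000, bin_width=200)
    assert np.allclose(
        prof["control"].dropna().values[::-1], prof_plus["control"].dropna().values
    )


def test_tss_profile_warns_without_genes(small_pipeline):
    with pytest.warns(RuntimeWarning, match="no genes"):
        prof = tss_profile(small_pipeline.matrix, pd.DataFrame(columns=["chrom", "tss", "strand"]))
    assert prof.empty
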