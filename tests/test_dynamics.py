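import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remethyl.dynamics import (
    DEFAULT_DYNAMICS,
    DynamicsParams,
    NoiseParams,
    Timeline,
    expected_trajectory,
    fit_dynamics,
    simulate_experiment,
    step_methylation,
)
from remethyl.genome import GenomeSpec, LocusClass, build_genome

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@pytest.mark.parametrize(
    "m,rho,delta,gate,expected",
    [
        (0.8, 0.0, 0.0, True, 0.4),  # passive halving per division
        (0.8, 0.0, 0.0, False, 0.4),
        (1.0, 1.0, 0.0, True, 1.0),  # perfect maintenance fixed point
        (0.9, 0.0, 0.25, True, 0.575),  # hand evaluation of the recurrence
        (0.0, 0.5, 0.3, False, 0.0),  # gate closed: no de novo from zero
    ],
)
def test_step_methylation_values(m, rho, delta, gate, expected):
    assert step_methylation(m, rho, delta, gate) == pytest.approx(expected)


@settings(max_examples=200, derandomize=True)
@given(m=unit, rho=unit, delta=unit, gate=st.booleans())
def test_step_methylation_stays_in_unit_interval(m, rho, delta, gate):
    assert 0.0 <= step_methylation(m, rho, delta, gate) <= 1.0


def test_step_grid_corners():
    grid = np.linspace(0, 1, 6)
    for m in grid:
        for rho in grid:
            for delta in grid:
                for gate in (True, False):
                    out = step_methylation(m, rho, delta, gate)
                    assert 0.0 <= out <= 1.0


def test_trajectory_closed_form_maintenance_off():
    # rho=0, gate open: m_t = delta + (m0 - delta) / 2^t
    p = DynamicsParams(m0=0.9, rho_on=0.0, delta=0.25, delta_on=0.25, theta=0.0)
    tl = Timeline(timepoints=("control", "d0"), divisions_off=3)
    traj = expected_trajectory(p, tl)
    assert traj["control"] == pytest.approx(0.9)
    assert traj["d0"] == pytest.approx(0.25 + 0.65 / 8)  # 0.33125
    # closed form agrees with iteration at every division count
    for t in range(1, 12):
        tl = Timeline(timepoints=("control", "d0"), divisions_off=t)
        assert expected_trajectory(p, tl)["d0"] == pytest.approx(
            0.25 + (0.9 - 0.25) / 2**t
        )


def test_unmethylated_state_is_immune():
    p = DynamicsParams(m0=0.0, rho_on=0.8, delta=0.0)
    traj = expected_trajectory(p, Timeline())
    assert all(v == 0.0 for v in traj.values())


def test_perfect_maintenance_is_constant():
    p = DynamicsParams(m0=0.73, rho_on=1.0, delta=0.0, theta=0.0)
    tl = Timeline()
    # off phase still halves; constancy holds when divisions_off = 0
    tl0 = Timeline(divisions_off=0)
    traj = expected_trajectory(p, tl0)
    assert all(v == pytest.approx(0.73) for v in traj.values())


def test_re_plateau_matches_delta_band():
    # with maintenance off and delta in [0.22, 0.35], retention at d0
    # approaches the plateau delta (22-35%)
    tl = Timeline()
    for delta in (0.22, 0.25, 0.30, 0.35):
        p = DynamicsParams(m0=0.9, rho_on=1.0, delta=delta, theta=0.0)
        d0 = expected_trajectory(p, tl)["d0"]
        assert delta <= d0 <= delta + 0.01


def test_gate_closed_trajectories_non_increasing():
    # with the gate shut (theta=1 means it never opens from m<1) and rho<1,
    # methylation can only decay
    tl = Timeline()
    for rho in (0.0, 0.5, 0.9):
        p = DynamicsParams(m0=0.8, rho_on=rho, delta=0.4, delta_on=0.4, theta=1.0)
        traj = expected_trajectory(p, tl)
        vals = [traj[tp] for tp in tl.timepoints]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


def _single_class_genome(n_loci, density, seed, cls=LocusClass.INTERGENIC):
    length = n_loci * (1000 + 1300) + 10_000
    spec = GenomeSpec(chromosomes=(("chr1", length),), rng_seed=seed)
    return build_genome(spec, {cls: n_loci}, cpg_density=density, hyper_fraction=0.0)


def test_simulated_means_match_expected_trajectory():
    # noise off except counting noise: pooled mean within 3 binomial SE
    loci, sites = _single_class_genome(200, 10, seed=1)
    params = {LocusClass.INTERGENIC: DynamicsParams(m0=0.9, rho_on=1.0, delta=0.02,
                                                    delta_on=0.02, theta=0.0)}
    tl = Timeline()
    noise = NoiseParams(mean_coverage=30, coverage_dispersion=5, site_jitter_sd=0.0)
    calls, manifest = simulate_experiment(
        loci, sites, params, tl, noise, {"control": 2, "d0": 2, "d21": 2}, seed=11
    )
    traj = expected_trajectory(params[LocusClass.INTERGENIC], tl)
    for tp in ("control", "d0", "d21"):
        reps = manifest.loc[manifest.timepoint == tp, "sample_id"]
        tot = sum(calls[s]["coverage"].sum() for s in reps)
        meth = sum(calls[s]["n_meth"].sum() for s in reps)
        m = meth / tot
        se = np.sqrt(max(traj[tp] * (1 - traj[tp]), 1e-12) / tot)
        assert abs(m - traj[tp]) <= 3 * se + 1e-9


def test_imprinted_allele_average_and_no_recovery():
    loci, sites = _single_class_genome(100, 10, seed=2, cls=LocusClass.IMPRINTED_GDMD)
    calls, manifest = simulate_experiment(loci, sites, seed=5)
    by_tp = {}
    for row in manifest.itertuples():
        c = calls[row.sample_id]
        by_tp.setdefault(row.timepoint, []).append(
            c["n_meth"].sum() / c["coverage"].sum()
        )
    control = np.mean(by_tp["control"])
    d21 = np.mean(by_tp["d21"])
    assert control == pytest.approx(0.5, abs=0.03)  # allele average of 1 and 0
    assert d21 < 0.05  # loss is permanent


def test_simulation_deterministic_under_seed():
    loci, sites = _single_class_genome(20, 5, seed=3)
    a, _ = simulate_experiment(loci, sites, seed=7)
    b, _ = simulate_experiment(loci, sites, seed=7)
    for s in a:
        assert a[s].equals(b[s])


def test_unknown_class_params_raise():
    loci, sites = _single_class_genome(5, 5, seed=4)
    with pytest.raises(KeyError):
        simulate_experiment(loci, sites, params_map={}, seed=0)


def test_fit_recovers_noiseless_parameters_exactly():
    tl = Timeline()
    for rho, delta, m0 in [(0.0, 0.3, 0.85), (0.9, 0.15, 0.8), (0.966, 0.12, 0.8)]:
        p = DynamicsParams(m0=m0, rho_on=rho, delta=delta, delta_on=delta, theta=0.0)
        traj = expected_trajectory(p, tl)
        fit = fit_dynamics(traj, tl)
        assert abs(fit.delta - delta) <= 1e-6
        assert abs(fit.m0 - m0) <= 1e-6
        if rho > 0:  # rho is not identifiable when recovery never rebuilds
            assert abs(fit.rho - rho) <= 1e-6


def test_fit_flags_constant_zero_trajectory():
    tl = Timeline()
    fit = fit_dynamics({tp: 0.0 for tp in tl.timepoints}, tl)
    assert fit.delta == 0.0
    assert not fit.identifiable


def test_fit_constant_one_trajectory():
    tl = Timeline()
    fit = fit_dynamics({tp: 1.0 for tp in tl.timepoints}, tl)
    assert fit.m0 == pytest.approx(1.0, abs=1e-6)
    # no loss at all requires maintenance ~1 or saturating de novo
    model_d0 = expected_trajectory(
        DynamicsParams(m0=fit.m0, rho_on=fit.rho, delta=fit.delta,
                       delta_on=fit.delta, theta=0.0),
        tl,
    )["d0"]
    assert model_d0 == pytest.approx(1.0, abs=1e-6)


def test_fit_recovers_parameters_from_stochastic_simulation():
    # Monte-Carlo oracle at fixed seed: pooled trajectory over 5,000 CpGs
    truth = DynamicsParams(m0=0.8, rho_on=0.966, delta=0.12, delta_on=0.12, theta=0.0)
    loci, sites = _single_class_genome(500, 10, seed=8)
    tl = Timeline()
    calls, manifest = simulate_experiment(
        loci,
        sites,
        {LocusClass.INTERGENIC: truth},
        tl,
        NoiseParams(),
        {tp: 2 for tp in tl.timepoints},
        seed=21,
    )
    observed = {}
    for tp in tl.timepoints:
        reps = manifest.loc[manifest.timepoint == tp, "sample_id"]
        tot = sum(calls[s]["coverage"].sum() for s in reps)
        meth = sum(calls[s]["n_meth"].sum() for s in reps)
        observed[tp] = meth / tot
    fit = fit_dynamics(observed, tl)
    assert abs(fit.delta - truth.delta) <= 0.05
    assert abs(fit.rho - truth.rho_on) <= 0.05
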