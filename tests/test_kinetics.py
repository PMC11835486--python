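"""Kinetics core: derivative algebra, integration, conservation, steady states."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mircompete import (
    RateSet,
    SpeciesSpec,
    SystemConfig,
    WT_RATES,
    SL_RATES,
    closed_form_diced_fraction,
    derivatives,
    run_to_steady_state,
    simulate,
    stall_demand,
)
from conftest import rk4_integrate

Q_WT = 0.0053 * 10439.0 / (0.0053 * 10439.0 + 0.0122 * (0.1340 + 10439.0))


def single(rates: RateSet, P0=1.0, D0=5.0) -> SystemConfig:
    return SystemConfig(species=(SpeciesSpec("s", P0, rates),), D0=D0)


# --- rate-set and config validation -----------------------------------------

@pytest.mark.parametrize("bad", [{"k_a": -1.0}, {"k_d": float("nan")}, {"k_b": float("inf")}])
def test_invalid_rates_rejected(bad):
    kwargs = {"k_a": 0.1, "k_b": 0.1, "k_c": 0.1, "k_d": 0.1, **bad}
    with pytest.raises(ValueError):
        RateSet(**kwargs)


def test_config_validation():
    sp = SpeciesSpec("a", 1.0, WT_RATES)
    with pytest.raises(ValueError):
        SystemConfig(species=(), D0=1.0)
    with pytest.raises(ValueError):
        SystemConfig(species=(sp, sp), D0=1.0)  # duplicate labels
    with pytest.raises(ValueError):
        SystemConfig(species=(sp,), D0=-1.0)


# --- derivatives -------------------------------------------------------------

def test_derivatives_zero_state_is_fixed_point(wt_config):
    assert np.all(derivatives(np.zeros(5), wt_config) == 0.0)


def test_derivatives_hand_substitution(wt_config):
    # P=1, D=5, PD=S=M=0: dP/dt = -(k_a + k_c) P D, dM/dt = 0
    state = np.array([1.0, 0.0, 0.0, 0.0, 5.0])
    d = derivatives(state, wt_config)
    assert d[0] == pytest.approx(-(0.0053 + 0.0122) * 1.0 * 5.0)  # -0.0875 nM/s
    assert d[0] == pytest.approx(-0.0875)
    assert d[3] == 0.0


def test_derivatives_no_dicer_freezes_system(wt_config):
    state = np.array([1.0, 0.0, 0.3, 0.2, 0.0])  # D = 0, PD = 0
    d = derivatives(state, wt_config)
    assert np.all(d == 0.0)


def test_derivatives_dimension_mismatch(wt_config):
    with pytest.raises(ValueError, match="shape"):
        derivatives(np.zeros(7), wt_config)


def test_derivatives_shared_pool_sums_species():
    cfg = SystemConfig(
        species=(SpeciesSpec("a", 1.0, WT_RATES), SpeciesSpec("b", 2.0, SL_RATES)),
        D0=5.0,
    )
    state = np.array([1.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 5.0])
    d = derivatives(state, cfg)
    expected_dD = -(0.0053 + 0.0122) * 1.0 * 5.0 - (0.0020 + 0.0343) * 2.0 * 5.0
    assert d[-1] == pytest.approx(expected_dD)


# --- simulate ----------------------------------------------------------------

def test_simulate_initial_point_and_wt_plateau(wt_config):
    traj = simulate(wt_config, 3600.0)
    assert traj.P[0, 0] == pytest.approx(1.0)
    assert traj.PD[0, 0] == traj.S[0, 0] == traj.M[0, 0] == 0.0
    assert traj.D[0] == pytest.approx(5.0)
    # closed-form absorption probability: Dicer never exhausted here
    assert traj.M[-1, 0] == pytest.approx(Q_WT, abs=1e-4)
    assert traj.M[-1, 0] == pytest.approx(0.3029, abs=2e-4)


def test_simulate_empty_substrate_pool():
    cfg = single(WT_RATES, P0=0.0)
    traj = simulate(cfg, 100.0)
    assert np.all(traj.M == 0.0)
    assert np.all(traj.D == pytest.approx(5.0))


def test_simulate_no_loss_pathway_matures_everything():
    cfg = single(RateSet(k_a=0.01, k_b=0.0, k_c=0.0, k_d=0.5), P0=1.0, D0=5.0)
    traj = simulate(cfg, 3600.0)
    assert traj.M[-1, 0] == pytest.approx(1.0, abs=1e-6)


def test_simulate_rejects_bad_horizon(wt_config):
    with pytest.raises(ValueError):
        simulate(wt_config, 0.0)


def test_simulate_rejects_isolated_flag(panel):
    from dataclasses import replace

    with pytest.raises(ValueError, match="shared"):
        simulate(replace(panel, shared_dicer=False), 10.0)


# --- conservation and non-negativity (property) ------------------------------

rate_st = st.floats(min_value=1e-4, max_value=100.0)
conc_st = st.floats(min_value=0.0, max_value=5.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    kas=st.lists(rate_st, min_size=1, max_size=3),
    kb=rate_st,
    kc=rate_st,
    kd=rate_st,
    p0=conc_st,
    d0=conc_st,
)
def test_conservation_random_configs(kas, kb, kc, kd, p0, d0):
    """Mass and Dicer conservation hold at every output point, any config."""
    species = tuple(
        SpeciesSpec(f"s{i}", p0, RateSet(ka, kb, kc, kd)) for i, ka in enumerate(kas)
    )
    cfg = SystemConfig(species=species, D0=d0)
    traj = simulate(cfg, 50.0, rtol=1e-8, atol=1e-10)
    mass_err, dicer_err = traj.conservation_errors()
    tol = 10 * (1e-10 + 1e-8 * max(p0 * len(kas) + d0, 1.0))
    assert mass_err < tol
    assert dicer_err < tol
    assert traj.P.min() >= -tol and traj.M.min() >= -tol and traj.D.min() >= -tol


@settings(max_examples=10, deadline=None, derandomize=True)
@given(
    ka=st.floats(min_value=1e-3, max_value=1.0),
    kb=st.floats(min_value=1e-3, max_value=1.0),
    kc=st.floats(min_value=1e-3, max_value=1.0),
    kd=st.floats(min_value=1e-3, max_value=10.0),
)
def test_simulate_agrees_with_fixed_step_rk4(ka, kb, kc, kd):
    """Adaptive solution matches an independent RK4 integration on 10 s."""
    cfg = single(RateSet(ka, kb, kc, kd), P0=1.0, D0=5.0)
    traj = simulate(cfg, 10.0, t_eval=[0.0, 10.0])
    # dt far inside RK4 stability for the fastest rate in this strategy
    y_rk4 = rk4_integrate(cfg, 10.0, dt=1e-3)
    adaptive = np.array([traj.P[-1, 0], traj.PD[-1, 0], traj.S[-1, 0], traj.M[-1, 0], traj.D[-1]])
    assert np.allclose(adaptive, y_rk4, atol=1e-4)


def test_simulate_agrees_with_rk4_at_wt_stiffness(wt_config):
    """The k_d ~ 1e4 rate needs dt ~ 1e-4 for explicit RK4 stability."""
    traj = simulate(wt_config, 10.0, t_eval=[0.0, 10.0])
    y_rk4 = rk4_integrate(wt_config, 10.0, dt=5e-5)
    adaptive = np.array([traj.P[-1, 0], traj.PD[-1, 0], traj.S[-1, 0], traj.M[-1, 0], traj.D[-1]])
    assert np.allclose(adaptive, y_rk4, atol=1e-4)


# --- steady state ------------------------------------------------------------

def test_steady_state_wt_oracle(wt_config):
    ss = run_to_steady_state(wt_config)
    assert ss.converged
    assert ss.M[0] == pytest.approx(Q_WT, abs=1e-4)
    assert ss.S[0] == pytest.approx(1.0 - Q_WT, abs=1e-4)
    assert ss.P[0] == pytest.approx(0.0, abs=1e-6)


def test_steady_state_no_enzyme():
    ss = run_to_steady_state(single(WT_RATES, D0=0.0))
    assert ss.converged
    assert ss.M[0] == 0.0 and ss.P[0] == 1.0


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    ka=st.floats(min_value=1e-3, max_value=1.0),
    kb=st.floats(min_value=1e-3, max_value=1.0),
    kc=st.floats(min_value=1e-3, max_value=1.0),
    kd=st.floats(min_value=1e-3, max_value=100.0),
)
def test_oracle_equivalence_unexhausted_dicer(ka, kb, kc, kd):
    """Steady M/P0 equals the closed form whenever stall demand < D0."""
    rates = RateSet(ka, kb, kc, kd)
    cfg = single(rates, P0=1.0, D0=5.0)
    assert stall_demand(cfg) < cfg.D0
    ss = run_to_steady_state(cfg)
    assert ss.converged
    assert ss.M[0] == pytest.approx(closed_form_diced_fraction(rates), abs=1e-4)


def test_complementary_exhaustion(panel):
    """At steady state either free Dicer or free pre-miRNA is gone, per species."""
    from dataclasses import replace

    for d0 in (0.5, 8.0):
        ss = run_to_steady_state(replace(panel, D0=d0))
        assert ss.converged
        assert np.all(ss.P * ss.D < 1e-6)


def test_panel_all_substrate_consumed_at_abundant_dicer(panel):
    """Stall demand ~5 nM < 8 nM: every species' free pre-miRNA vanishes."""
    assert stall_demand(panel) < 8.0
    ss = run_to_steady_state(panel)  # D0 = 8
    assert np.sum(ss.S) < 8.0
    assert np.all(ss.P < 1e-6)


def test_steady_mature_monotone_in_ka_and_kc():
    base = WT_RATES
    m = lambda r: run_to_steady_state(single(r)).M[0]
    m_base = m(base)
    assert m(base.scaled("k_a", 4.0)) >= m_base - 1e-9
    assert m(base.scaled("k_c", 4.0)) <= m_base + 1e-9


# --- closed form -------------------------------------------------------------

def test_closed_form_wt_value():
    assert closed_form_diced_fraction(WT_RATES) == pytest.approx(0.3029, abs=2e-4)


def test_closed_form_edges():
    assert closed_form_diced_fraction(RateSet(0.1, 0.2, 0.0, 0.3)) == 1.0
    assert closed_form_diced_fraction(RateSet(0.0, 0.2, 0.1, 0.3)) == 0.0
    with pytest.raises(ValueError):
        # k_a = k_c = 0: no binding pathway at all, denominator vanishes
        closed_form_diced_fraction(RateSet(0.0, 0.2, 0.0, 0.3))
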