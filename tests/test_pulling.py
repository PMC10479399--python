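"""Stochastic bead--spring pulling simulations."""

import math

import numpy as np
import pytest

from talin_clutch.kinetics import BellParams
from talin_clutch.mechanics import ChainConfig
from talin_clutch.pulling import (
    SimParams,
    init_chain,
    make_state,
    run_ensemble,
    run_single,
    step,
)

# ensembles in this module use the cheap-but-converged numerics pairing
# (zeta = 1e-3 pN s/nm, dt = 1e-5 s); the friction/timestep-insensitivity
# test below checks it against the reference pairing (1e-4, 1e-6 s)
FAST = dict(zeta=1e-3, dt_sim=1e-5)

SLOW_KINETICS = BellParams(k0=1e-12, dx=0.1)  # effectively frozen bonds


class TestInitChain:
    def test_vertical_geometry(self, mech):
        cfg = ChainConfig(n_total=12, theta0=90, v_retro=20)
        pos = init_chain(cfg, mech, SimParams())
        assert pos.shape == (15, 2)
        assert pos[-1, 1] == pytest.approx(28.0)
        assert abs(pos[-1, 0]) < 1e-9

    def test_diagonal_geometry(self, mech):
        cfg = ChainConfig(n_total=12, theta0=45, v_retro=20)
        pos = init_chain(cfg, mech, SimParams())
        end = pos[-1] - pos[0]
        assert end[0] == pytest.approx(end[1])
        assert np.hypot(*end) == pytest.approx(28.0)

    def test_compliance_adds_two_beads(self, mech):
        cfg = ChainConfig(n_total=12, theta0=45, v_retro=20)
        rigid = init_chain(cfg, mech, SimParams())
        soft = init_chain(cfg, mech, SimParams(compliance_k3=1e4))
        assert soft.shape[0] == rigid.shape[0] + 2


class TestStep:
    def test_equilibrium_is_fixed_point(self, mech):
        cfg = ChainConfig(n_total=4, theta0=45, v_retro=0)
        sim = SimParams()
        state = make_state(cfg, mech, sim)
        before = state.positions.copy()
        for _ in range(10):
            step(state, cfg, mech, sim)
        assert np.allclose(state.positions, before, atol=1e-12)

    def test_relaxation_speed(self, mech):
        # a folded segment stretched 1 nm pulls its bead at 10 pN / zeta
        cfg = ChainConfig(n_total=1, theta0=90, v_retro=0)
        sim = SimParams(zeta=1e-4, dt_sim=1e-6)
        state = make_state(cfg, mech, sim)
        state.positions[1, 1] += 1.0  # stretch integrin linker by 1 nm
        p_before = state.positions[1].copy()
        step(state, cfg, mech, sim)
        moved = state.positions[1] - p_before
        # net force ~ 10 pN down from the stretched lower segment plus
        # 10 pN down from the compressed... compression is slack, so 10 pN
        speed = abs(moved[1]) / sim.dt_sim
        assert speed == pytest.approx(1e5, rel=0.05)

    def test_instability_detected(self, mech):
        cfg = ChainConfig(n_total=2, theta0=90, v_retro=0)
        sim = SimParams(zeta=1e-4, dt_sim=1e-6)
        state = make_state(cfg, mech, sim)
        state.positions[1, 1] += 500.0  # absurd stretch
        from talin_clutch.pulling import SimulationInstabilityError

        with pytest.raises(SimulationInstabilityError):
            step(state, cfg, mech, sim)

    def test_tension_equilibrates_quickly(self, mech):
        # after a perturbation, tension spreads uniform along the chain in
        # a time ~ zeta/k = 1e-5 s, far below kinetic timescales
        cfg = ChainConfig(n_total=6, theta0=45, v_retro=0)
        sim = SimParams(zeta=1e-4, dt_sim=1e-6)
        state = make_state(cfg, mech, sim)
        u = np.array([math.cos(math.radians(45)), math.sin(math.radians(45))])
        state.positions[-1] += 2.0 * u  # stretch the whole chain
        for _ in range(2000):  # 2e-3 s
            step(state, cfg, mech, sim)
        tau = state.segment_tensions(mech)
        assert tau.std() / tau.mean() < 0.01


class TestRunSingle:
    def test_determinism(self, mech, unfold_default, unbind_slip, chain_12):
        sim = SimParams(**FAST, t_max=60)
        t1 = run_single(chain_12, mech, sim, unfold_default, unbind_slip, seed=5)
        t2 = run_single(chain_12, mech, sim, unfold_default, unbind_slip, seed=5)
        assert t1.unbinding_time == t2.unbinding_time
        assert t1.work == t2.work
        assert np.array_equal(t1.event_times, t2.event_times)

    def test_event_log_structure(self, mech, unfold_default, unbind_slip):
        cfg = ChainConfig(n_total=12, n_unfoldable=12, theta0=45, v_retro=40)
        sim = SimParams(**FAST, t_max=120)
        for seed in range(8):
            tr = run_single(cfg, mech, sim, unfold_default, unbind_slip, seed=seed)
            assert np.all(np.diff(tr.event_times) > 0) or tr.n_unfolds <= 1
            assert tr.n_unfolds <= 12
            assert tr.work >= 0
            if not tr.censored:
                assert tr.unbinding_time <= 120

    def test_censoring_guard(self, mech, unbind_slip):
        cfg = ChainConfig(n_total=2, n_unfoldable=0, theta0=45, v_retro=0)
        sim = SimParams(**FAST, t_max=0.01)
        tr = run_single(cfg, mech, sim, SLOW_KINETICS, SLOW_KINETICS, seed=1)
        assert tr.censored
        assert tr.unbinding_time == pytest.approx(0.01, rel=1e-6)

    def test_work_energy_inequality(self, mech):
        # dissipation is non-negative: accumulated work on the chain must
        # always exceed the stored elastic energy (no events, pure pull)
        cfg = ChainConfig(n_total=4, n_unfoldable=0, theta0=45, v_retro=40)
        sim = SimParams(zeta=1e-3, dt_sim=1e-5)
        state = make_state(cfg, mech, sim)
        for k in range(20):
            for _ in range(500):
                step(state, cfg, mech, sim)
            assert state.work >= state.elastic_energy(mech) - 1e-9


class TestEnsembles:
    def test_zero_force_exponential_lifetime(self, mech, unfold_default, unbind_slip):
        cfg = ChainConfig(n_total=12, n_unfoldable=0, theta0=45, v_retro=0)
        sim = SimParams(**FAST, t_max=120)
        df = run_ensemble(cfg, mech, sim, unfold_default, unbind_slip, n=80, base_seed=2)
        m, se = df.t_unbind_s.mean(), df.t_unbind_s.sem()
        assert abs(m - 1 / 0.17) < 3 * se

    def test_single_trace_summary(self, mech, unfold_default, unbind_slip, chain_12):
        sim = SimParams(**FAST, t_max=60)
        df = run_ensemble(chain_12, mech, sim, unfold_default, unbind_slip, n=1, base_seed=9)
        tr = run_single(chain_12, mech, sim, unfold_default, unbind_slip, seed=10)
        assert len(df) == 1
        assert df.loc[0, "t_unbind_s"] == tr.unbinding_time

    def test_friction_timestep_insensitivity(self, mech, unfold_default, unbind_slip):
        # overdamped quasi-static regime: halving relaxation separation
        # changes nothing beyond noise
        cfg = ChainConfig(n_total=12, n_unfoldable=0, theta0=45, v_retro=40)
        ref = run_ensemble(
            cfg, mech, SimParams(zeta=1e-4, dt_sim=1e-6, t_max=30),
            unfold_default, unbind_slip, n=25, base_seed=3,
        )
        fast = run_ensemble(
            cfg, mech, SimParams(zeta=1e-3, dt_sim=1e-5, t_max=30),
            unfold_default, unbind_slip, n=25, base_seed=3,
        )
        se = math.hypot(ref.t_unbind_s.sem(), fast.t_unbind_s.sem())
        assert abs(ref.t_unbind_s.mean() - fast.t_unbind_s.mean()) < 3 * se

    def test_stiff_compliance_matches_rigid(self, mech, unfold_default, unbind_slip):
        cfg = ChainConfig(n_total=12, n_unfoldable=2, theta0=45, v_retro=40)
        rigid = run_ensemble(
            cfg, mech, SimParams(**FAST, t_max=60),
            unfold_default, unbind_slip, n=30, base_seed=4,
        )
        stiff = run_ensemble(
            cfg, mech, SimParams(zeta=1e-3, dt_sim=2e-6, t_max=60, compliance_k3=1e5),
            unfold_default, unbind_slip, n=30, base_seed=4,
        )
        se = math.hypot(rigid.t_unbind_s.sem(), stiff.t_unbind_s.sem())
        assert abs(rigid.t_unbind_s.mean() - stiff.t_unbind_s.mean()) < 3 * se

    def test_stability_validation(self, mech):
        with pytest.raises(ValueError):
            SimParams(zeta=1e-4, dt_sim=1e-6, compliance_k3=1e6).check_stability(mech)
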