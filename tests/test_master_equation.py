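"""Master-equation solver: stepping kernels, observables, sweeps, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from talin_clutch import master_equation as me
from talin_clutch.kinetics import BellParams, SubdomainSpec
from talin_clutch.mechanics import ChainConfig


class TestStepProbabilities:
    def test_zero_rate(self):
        assert me.step_probabilities(0.0, 1.0) == 0.0

    def test_measured_point(self):
        assert me.step_probabilities(0.17, 1.0) == pytest.approx(0.15633, abs=1e-4)

    def test_saturation(self):
        assert me.step_probabilities(1e4, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            me.step_probabilities([0.1], 0.0)
        with pytest.raises(ValueError):
            me.step_probabilities([-0.1], 1.0)


class TestUnfoldTransitionMatrix:
    def test_no_unfolding(self):
        row = me.unfold_transition_matrix(5, 2, 0.0)
        assert row[2] == 1.0 and row.sum() == 1.0

    def test_binomial_row(self):
        row = me.unfold_transition_matrix(2, 0, 0.1)
        assert np.allclose(row, [0.81, 0.18, 0.01])

    @given(
        M=st.integers(min_value=0, max_value=15),
        p=st.floats(min_value=0, max_value=0.999),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_rows_are_pmf(self, M, p, data):
        i = data.draw(st.integers(min_value=0, max_value=M))
        row = me.unfold_transition_matrix(M, i, p)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(row >= 0)
        assert np.all(row[:i] == 0)


class TestSolve:
    def test_constant_rate_limit(self, mech, unfold_default, unbind_slip):
        # M = 0, no flow: pure exponential with the zero-force rate
        cfg = ChainConfig(n_total=12, n_unfoldable=0, theta0=45, v_retro=0)
        res = me.solve(cfg, mech, unfold_default, unbind_slip, dt=1e-3)
        obs = res.observables()
        assert obs.mean_clutch_duration == pytest.approx(1 / 0.17, rel=0.01)

    def test_probability_bounds_and_conservation(self, mech, unfold_default, unbind_slip, chain_12):
        res = me.solve(chain_12, mech, unfold_default, unbind_slip, dt=1e-3)
        assert np.all(res.P >= -1e-12)
        assert np.all(res.P <= 1 + 1e-12)
        pu = res.P_unbound
        assert np.all(np.diff(pu) >= -1e-12)
        # accumulated unbinding mass accounts for all lost probability
        recon = np.cumsum(res.unbind_mass.sum(axis=1))
        assert np.max(np.abs(recon[:-1] - pu[1:])) < 1e-9

    def test_heterogeneous_matches_homogeneous_when_identical(
        self, mech, unbind_slip, unfold_default
    ):
        cfg = ChainConfig(n_total=6, n_unfoldable=4, theta0=45, v_retro=20)
        spec = SubdomainSpec.uniform(6, 4)
        rh = me.solve(cfg, mech, spec, unbind_slip, dt=1e-3, t_max=2.0, p_terminate=1.1)
        rm = me.solve(cfg, mech, unfold_default, unbind_slip, dt=1e-3, t_max=2.0, p_terminate=1.1)
        assert np.max(np.abs(rh.P - rm.P)) < 1e-8

    def test_heterogeneous_parameters_matter(self, mech, unbind_slip):
        # distinct per-subdomain barrier distances change the state mix
        cfg = ChainConfig(n_total=4, n_unfoldable=3, theta0=45, v_retro=20)
        uniform = SubdomainSpec.uniform(4, 3)
        mixed = SubdomainSpec(
            params=(
                BellParams(1e-4, 6.0), BellParams(1e-4, 3.0),
                BellParams(1e-4, 2.0), BellParams(1e-4, 4.0),
            ),
            unfoldable=(True, True, True, False),
        )
        ru = me.solve(cfg, mech, uniform, unbind_slip, dt=1e-3, t_max=2.0, p_terminate=1.1)
        rx = me.solve(cfg, mech, mixed, unbind_slip, dt=1e-3, t_max=2.0, p_terminate=1.1)
        assert np.max(np.abs(ru.P - rx.P)) > 1e-4

    def test_dt_convergence(self, mech, unfold_default, unbind_slip):
        cfg = ChainConfig(n_total=12, n_unfoldable=2, theta0=45, v_retro=20)
        d1 = me.solve(cfg, mech, unfold_default, unbind_slip, dt=1e-3).observables()
        d2 = me.solve(cfg, mech, unfold_default, unbind_slip, dt=5e-4).observables()
        assert d2.mean_clutch_duration == pytest.approx(
            d1.mean_clutch_duration, rel=5e-3
        )

    def test_state_space_guard(self, mech, unbind_slip):
        cfg = ChainConfig(n_total=25, n_unfoldable=21, theta0=45, v_retro=20)
        with pytest.raises(ValueError):
            me.solve(cfg, mech, SubdomainSpec.uniform(25, 21), unbind_slip)


class TestObservables:
    def test_zero_flow_zero_work(self, mech, unfold_default, unbind_slip):
        cfg = ChainConfig(n_total=12, n_unfoldable=0, theta0=45, v_retro=0)
        obs = me.solve(cfg, mech, unfold_default, unbind_slip, dt=1e-3).observables()
        assert obs.mean_work == 0.0
        assert obs.mean_unbind_displacement == 0.0

    def test_displacement_time_identity(self, mech, unfold_default, unbind_slip, chain_12):
        obs = me.solve(chain_12, mech, unfold_default, unbind_slip, dt=1e-3).observables()
        assert obs.mean_unbind_displacement == pytest.approx(
            chain_12.v_retro * obs.mean_clutch_duration, rel=1e-12
        )

    def test_densities_integrate_to_p_unbound(self, mech, unfold_default, unbind_slip, chain_12):
        res = me.solve(chain_12, mech, unfold_default, unbind_slip, dt=1e-3)
        obs = res.observables()
        d = obs.distributions
        assert np.sum(d.time_density) * res.dt == pytest.approx(
            obs.p_unbound_end, abs=1e-6
        )
        dx = d.displacement_grid[1] - d.displacement_grid[0]
        assert np.sum(d.displacement_density) * dx == pytest.approx(
            obs.p_unbound_end, abs=1e-6
        )
        assert d.fmax_hist.sum() == pytest.approx(obs.p_unbound_end, abs=1e-6)

    def test_partial_run_warns(self, mech, unfold_default, unbind_slip, chain_12):
        res = me.solve(chain_12, mech, unfold_default, unbind_slip, dt=1e-3, t_max=0.5)
        with pytest.warns(UserWarning, match="not converged"):
            obs = res.observables()
        assert obs.partial

    def test_summary_text(self, mech, unfold_default, unbind_slip, chain_12):
        res = me.solve(chain_12, mech, unfold_default, unbind_slip, dt=1e-3)
        s = res.summary()
        assert "mean clutch duration" in s and "M = 12" in s


class TestSweep:
    def test_single_point_equals_direct(self, mech, unfold_default, unbind_slip):
        cfg = ChainConfig(n_total=12, n_unfoldable=3, theta0=45, v_retro=20)
        tab = me.sweep(cfg, mech, unfold_default, unbind_slip, vary={"n_unfoldable": [3]})
        direct = me.solve(cfg, mech, unfold_default, unbind_slip, dt=1e-3).observables()
        assert len(tab) == 1
        assert tab.loc[0, "mean_clutch_duration_s"] == pytest.approx(
            direct.mean_clutch_duration, rel=1e-12
        )

    def test_bad_field(self, mech, unfold_default, unbind_slip, chain_12):
        with pytest.raises(ValueError):
            me.sweep(chain_12, mech, unfold_default, unbind_slip, vary={"zeta": [1]})


class TestCalibration:
    def test_single_grid_value(self, mech, unfold_default, unbind_slip):
        cfg = ChainConfig(n_total=12, n_unfoldable=2, theta0=45, v_retro=20)
        res = me.solve(cfg, mech, unfold_default, unbind_slip, dt=1e-3)
        d = res.observables().distributions
        edges = np.arange(0, 200, 10.0)
        counts, _ = np.histogram(
            d.displacement_grid, bins=edges, weights=d.time_density * res.dt
        )
        best, table = me.calibrate_dx_unbind(
            edges, counts, [0.4], cfg, mech, unfold_default
        )
        assert best == 0.4
        assert len(table) == 1

    def test_larger_dx_unbinds_earlier(self, mech, unfold_default):
        cfg = ChainConfig(n_total=12, n_unfoldable=2, theta0=45, v_retro=20)
        means = []
        for dx in (0.3, 0.8):
            obs = me.solve(cfg, mech, unfold_default, BellParams(0.17, dx), dt=1e-3).observables()
            means.append(obs.mean_unbind_displacement)
        assert means[1] < means[0]

    def test_empty_target_rejected(self, mech, unfold_default):
        cfg = ChainConfig(n_total=12, n_unfoldable=2)
        with pytest.raises(ValueError):
            me.calibrate_dx_unbind(
                np.arange(0, 100, 10.0), np.zeros(9), [0.5], cfg, mech, unfold_default
            )
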