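"""SiMS track classification, flow-onset detection, survival rates,
flux balance and force bookkeeping."""

import numpy as np
import pytest

from talin_clutch.sims import (
    ForceBookkeeping,
    SpeckleTrack,
    TrackFormatError,
    classify_tracks,
    clutch_flux_balance,
    derive_rate_constants,
    detect_flow_onset,
    force_bookkeeping,
    km_exponential_rate,
)

CLUTCH_RATES = {"k_a": 0.0548, "k_b": 0.374, "k_c": 0.680, "k_d": 0.0315}
RATES_ALL = dict(CLUTCH_RATES, k_2=0.0324, k_4=0.00694)


def make_track(x, dt=2.0, tid="t", sd=18.6):
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) * dt
    return SpeckleTrack(id=tid, frame_interval=dt, t=t, x=x, y=np.zeros_like(x),
                        localization_sd=sd)


def noiseless_cases():
    """~50 noiseless single-mode/switching fixtures with known labels."""
    cases = []
    for speed in (45, 60, 80, 120):
        for n in (5, 10, 25):
            cases.append((np.arange(n) * speed, "flowing"))
            cases.append((np.zeros(n), "stationary"))
    for speed in (60, 90):
        for n_stat in (5, 15, 30):
            for n_flow in (5, 15, 30):
                x = np.concatenate([np.zeros(n_stat), np.arange(1, n_flow + 1) * speed])
                cases.append((x, "switching"))
                cases.append((x[::-1] * -1 + x[-1], "switching"))  # flow then stop
    for n in (6, 12):
        cases.append((-np.arange(n) * 60.0, "unclassified"))  # counter-flow drift
    return cases


class TestClassifyCoarse:
    @pytest.mark.parametrize("x,expected", noiseless_cases())
    def test_noiseless_exact(self, x, expected):
        label = classify_tracks([make_track(x)], mode="coarse_2s")[0]
        assert label.category == expected

    def test_short_track_excluded(self):
        label = classify_tracks([make_track([0.0, 0.0])], mode="coarse_2s")[0]
        assert label.category == "excluded"
        assert "lifetime" in label.reason

    def test_segments_tile_track(self):
        x = np.concatenate([np.zeros(20), np.arange(1, 21) * 60.0])
        label = classify_tracks([make_track(x)], mode="coarse_2s")[0]
        spans = sorted(label.segments)
        assert spans[0][0] == 0
        assert spans[-1][1] == len(x) - 1  # intervals
        for (a, b, _), (c, d, _) in zip(spans, spans[1:]):
            assert b == c  # no overlap, no gap

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_tracks([make_track(np.zeros(10), dt=0.1)], mode="coarse_2s")


class TestClassifyFast:
    def test_fast_switching(self, rng):
        # 40 stationary frames then steady flow, mild noise
        x = np.concatenate([np.zeros(40), np.arange(1, 41) * 3.0 + 20])
        x = x + rng.normal(0, 5, x.size)
        label = classify_tracks([make_track(x, dt=0.1, sd=5)], mode="fast_100ms")[0]
        assert label.category == "switching"

    def test_fast_back_and_forth(self, rng):
        x = np.concatenate(
            [np.zeros(30), np.linspace(0, 60, 15), np.full(40, 0.0)]
        ) + rng.normal(0, 4, 85)
        label = classify_tracks([make_track(x, dt=0.1, sd=4)], mode="fast_100ms")[0]
        assert label.category == "back_and_forth"

    def test_fast_stationary(self, rng):
        x = rng.normal(0, 5, 80)
        label = classify_tracks([make_track(x, dt=0.1, sd=5)], mode="fast_100ms")[0]
        assert label.category == "stationary"


class TestDetectFlowOnset:
    def test_no_detection_on_stationary(self, rng):
        x = rng.normal(0, 18.6, 100)
        r = detect_flow_onset(make_track(x, dt=0.1))
        assert r is not None and r.t_detect is None

    def test_jump_fixture(self, rng):
        # 30 stationary frames (sigma = 5), instantaneous 100 nm jump,
        # then steady 30 nm/s flow
        sigma = 5.0
        n_stat = 30
        flow = 100 + np.arange(40) * 3.0
        x = np.concatenate([np.zeros(n_stat), flow]) + rng.normal(0, sigma, 70)
        r = detect_flow_onset(make_track(x, dt=0.1, sd=sigma))
        assert r.detect_index == n_stat  # first post-jump frame
        assert r.delta_x == pytest.approx(100.0, abs=2 * sigma)

    def test_short_track_not_applicable(self):
        assert detect_flow_onset(make_track(np.zeros(8), dt=0.1)) is None

    def test_noiseless_jump_detects(self):
        x = np.concatenate([np.zeros(20), np.full(20, 50.0)])
        r = detect_flow_onset(make_track(x, dt=0.1, sd=0))
        assert r.detect_index == 20
        assert r.delta_x == pytest.approx(50.0, abs=1e-6)


class TestKMExponentialRate:
    def test_estimator_consistency(self, rng):
        d = rng.exponential(1 / 0.17, 10_000)
        est = km_exponential_rate(d)
        assert est.rate == pytest.approx(0.17, rel=0.03)
        assert est.rate_mle == pytest.approx(0.17, rel=0.03)
        assert est.ci_low < 0.17 < est.ci_high

    def test_bleach_correction_arithmetic(self, rng):
        d = rng.exponential(1 / 0.1736, 20_000)
        raw = km_exponential_rate(d)
        corr = km_exponential_rate(d, bleach_per_frame=0.0071, frame_interval=2.0)
        assert corr.rate == pytest.approx(raw.rate - 0.00355, abs=1e-12)
        assert corr.rate == pytest.approx(0.170, abs=0.005)
        assert corr.bleach_corrected

    def test_censored_bias_bound(self, rng):
        d = rng.exponential(1 / 0.17, 500)
        cens = rng.random(500) < 0.15
        obs = np.where(cens, d * rng.random(500), d)
        est = km_exponential_rate(obs, cens)
        assert est.rate == pytest.approx(0.17, rel=0.10)

    def test_all_censored_error(self):
        with pytest.raises(ValueError):
            km_exponential_rate([1.0, 2.0], [True, True])

    def test_single_event_defined(self):
        est = km_exponential_rate([4.0], [False])
        assert np.isfinite(est.rate)
        assert est.n_events == 1


class TestFluxBalance:
    def test_printed_rates(self):
        sol = clutch_flux_balance(57.0, RATES_ALL)
        assert sol.C == pytest.approx(4.1, abs=0.2)
        assert 38.0 < sol.F < 40.0
        assert max(abs(r) for r in sol.residuals) < 1e-9

    def test_no_entry_trivial(self):
        sol = clutch_flux_balance(
            57.0, {"k_a": 0, "k_b": 0.374, "k_c": 0.680, "k_d": 0, "k_2": 0, "k_4": 0}
        )
        assert sol.C == 0 and sol.F == 0 and sol.X == 0

    def test_equation_choice_invariance(self):
        # oracle: solve using the stationary-state balance + flux closure
        # instead of the clutch balance used internally
        sol = clutch_flux_balance(57.0, RATES_ALL)
        ka, kb, kc, kd = (RATES_ALL[k] for k in ("k_a", "k_b", "k_c", "k_d"))
        k2, k4 = RATES_ALL["k_2"], RATES_ALL["k_4"]
        S = 57.0
        # stationary balance: -ka S + kb C + X = 0 with X = k2 S - k4 F
        # flowing balance:    kc C - kd F - X = 0
        A = np.array([[kb, -k4], [kc, -(kd - k4)]])
        b = np.array([ka * S - k2 * S, k2 * S])
        C, F = np.linalg.solve(A, b)
        assert sol.C == pytest.approx(C, abs=1e-9)
        assert sol.F == pytest.approx(F, abs=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            clutch_flux_balance(0.0, RATES_ALL)
        with pytest.raises(ValueError):
            clutch_flux_balance(57.0, {"k_a": 1})


class TestDeriveRates:
    def test_measured_duration(self):
        r = derive_rate_constants(1.47, 55, 100)
        assert r["k_c"] == pytest.approx(0.680, abs=5e-4)
        assert r["k_b"] == pytest.approx(0.374, abs=5e-4)

    def test_trivial(self):
        assert derive_rate_constants(2.0, 0, 1)["k_c"] == 0.5

    def test_no_switches(self):
        with pytest.raises(ZeroDivisionError):
            derive_rate_constants(1.0, 3, 0)


class TestForceBookkeeping:
    def test_molecule_count(self):
        rep = force_bookkeeping(ForceBookkeeping(talin_concentration_uM=3.0))
        assert rep["molecules_per_cell"][0] == pytest.approx(1.2e6, rel=0.03)

    def test_total_force(self):
        rep = force_bookkeeping(ForceBookkeeping())
        assert rep["total_force_pN"] == (4500.0, 4500.0)

    def test_per_speckle_and_per_clutch(self):
        rep = force_bookkeeping(ForceBookkeeping())
        lo, hi = rep["force_per_speckle_pN"]
        assert hi == pytest.approx(0.9, abs=0.05)
        assert lo == pytest.approx(0.55, abs=0.05)
        clo, chi = rep["force_per_clutch_pN"]
        assert chi == pytest.approx(22.0, abs=1.0)
        assert clo == pytest.approx(13.0, abs=1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            ForceBookkeeping(cytosol_volume_pL=0)
        with pytest.raises(ValueError):
            ForceBookkeeping(clutch_fraction=1.5)


class TestSpeckleTrack:
    def test_ragged_interval_rejected(self):
        with pytest.raises(TrackFormatError):
            SpeckleTrack(id="x", frame_interval=2.0, t=[0, 2, 5], x=[0, 0, 0], y=[0, 0, 0])

    def test_flow_axis_normalised(self):
        tr = SpeckleTrack(
            id="x", frame_interval=2.0, t=[0, 2], x=[0, 1], y=[0, 1],
            flow_axis=(3.0, 4.0),
        )
        assert np.hypot(*tr.flow_axis) == pytest.approx(1.0)
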