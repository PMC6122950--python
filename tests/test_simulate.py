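"""Event-time simulator and instrument renderers."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import kstest

from ejectkin.itc import J_PER_UCAL
from ejectkin.simulate import (
    InstrumentModel,
    SAXSConfig,
    SimulationConfig,
    arrhenius_rate,
    simulate_ejection_times,
    synthesize_dp_trace,
    synthesize_enthalpy_series,
    synthesize_ls_trace,
    synthesize_saxs_series,
    tstar_for_mg,
)

BASE = SimulationConfig(n_virions=2000, phi_fast=0.5, slow_delay_scale=40.0, noise_sd=0.0, seed=7)


class TestEventSimulation:
    def test_empty_population(self):
        events = simulate_ejection_times(replace(BASE, n_virions=0))
        assert events.n == 0

    def test_degenerate_jitter_all_start_at_zero(self):
        cfg = replace(BASE, phi_fast=1.0, jitter_max=0.0)
        events = simulate_ejection_times(cfg)
        assert np.all(events.start_times == 0.0)
        assert np.all(events.states == "fluid")

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_virions=-1)
        with pytest.raises(ValueError):
            SimulationConfig(temperature_C=-300.0)
        with pytest.raises(ValueError):
            SimulationConfig(phi_fast=1.5)

    def test_solid_delay_mean_matches_arrhenius_rate(self):
        # closed-form oracle: exponential delays have mean 1/k(T)
        cfg = SimulationConfig(
            n_virions=100000, phi_fast=0.0, slow_delay_scale=None,
            temperature_C=30.0, noise_sd=0.0, seed=11,
        )
        k = cfg.solid_rate()
        events = simulate_ejection_times(cfg)
        delays = events.start_times - cfg.dead_time
        se = (1 / k) / np.sqrt(cfg.n_virions)
        assert abs(delays.mean() - 1 / k) < 3 * se

    def test_solid_survival_is_exponential(self):
        cfg = SimulationConfig(n_virions=100000, phi_fast=0.0, slow_delay_scale=50.0, seed=3)
        events = simulate_ejection_times(cfg)
        stat = kstest(events.start_times - cfg.dead_time, "expon", args=(0, 50.0)).statistic
        assert stat < 0.02

    def test_rate_strictly_increases_with_temperature(self):
        A, Ea = 1e10, 1.2e-19
        rates = [arrhenius_rate(T, A, Ea) for T in (15.0, 25.0, 35.0, 45.0)]
        assert np.all(np.diff(rates) > 0)

    def test_seed_determinism_bytewise(self):
        cfg = replace(BASE, noise_sd=0.0005)
        t1 = synthesize_dp_trace(simulate_ejection_times(cfg))
        t2 = synthesize_dp_trace(simulate_ejection_times(cfg))
        assert t1.power.tobytes() == t2.power.tobytes()
        assert t1.time.tobytes() == t2.time.tobytes()


class TestDPTrace:
    def test_single_virion_area_conserved_under_convolution(self):
        cfg = replace(BASE, n_virions=1, phi_fast=1.0, jitter_max=0.0)
        trace = synthesize_dp_trace(simulate_ejection_times(cfg))
        got = np.trapezoid(trace.power, trace.time) * J_PER_UCAL
        assert got == pytest.approx(cfg.dH_per_virion, rel=1e-3)

    def test_population_heat_conservation(self):
        trace = synthesize_dp_trace(simulate_ejection_times(BASE))
        got = np.trapezoid(trace.power, trace.time) * J_PER_UCAL
        assert got == pytest.approx(BASE.n_virions * BASE.dH_per_virion, rel=1e-3)

    def test_irf_identity_limit(self):
        # τ → 0 (τ = dt/100): convolved trace equals the bare pulse sum
        cfg = replace(BASE, n_virions=200, seed=2)
        events = simulate_ejection_times(cfg)
        dt = cfg.sampling_dt
        sharp = InstrumentModel("itc", irf_tau=dt / 100, sampling_dt=dt, noise_sd=0.0)
        wide = InstrumentModel("itc", irf_tau=dt / 1e6, sampling_dt=dt, noise_sd=0.0)
        a = synthesize_dp_trace(events, sharp, t_max=300.0)
        b = synthesize_dp_trace(events, wide, t_max=300.0)
        rms = np.sqrt(np.mean((a.power - b.power) ** 2))
        assert rms < 0.01 * np.max(np.abs(b.power))

    def test_empty_event_set_gives_baseline(self):
        cfg = replace(BASE, n_virions=0)
        trace = synthesize_dp_trace(simulate_ejection_times(cfg))
        assert np.all(trace.power == 0.0)

    def test_instrument_kind_checked(self):
        events = simulate_ejection_times(BASE)
        with pytest.raises(ValueError):
            synthesize_dp_trace(events, InstrumentModel("ls"))


class TestLSTrace:
    def test_counting_oracle_when_no_condensate(self):
        events = simulate_ejection_times(BASE)
        trace = synthesize_ls_trace(events, condensate_weight=0.0)
        assert np.allclose(trace.intensity, events.filled_fraction(trace.time))

    def test_flat_when_nothing_ejects(self):
        cfg = replace(BASE, phi_fast=0.0, slow_delay_scale=1e9)
        events = simulate_ejection_times(cfg)
        trace = synthesize_ls_trace(events, t_max=500.0)
        assert np.all(trace.intensity == 1.0)

    def test_monotone_nonincreasing_for_unit_weight(self):
        events = simulate_ejection_times(BASE)
        for w in (0.3, 1.0):
            trace = synthesize_ls_trace(events, condensate_weight=w)
            assert np.all(np.diff(trace.intensity) <= 1e-12)

    def test_condensate_slows_apparent_decay(self):
        events = simulate_ejection_times(BASE)
        bare = synthesize_ls_trace(events, condensate_weight=0.0, t_max=600.0)
        smeared = synthesize_ls_trace(events, condensate_weight=0.5, t_max=600.0)
        assert np.all(smeared.intensity >= bare.intensity - 1e-12)


class TestSAXSSeries:
    def test_frame_zero_peak_area_matches_quadrature(self):
        cfg = replace(BASE, phi_fast=0.0, slow_delay_scale=500.0, dead_time=5.0)
        events = simulate_ejection_times(cfg)
        sx = SAXSConfig(t_max=10.0, noise_sd=0.0)
        series = synthesize_saxs_series(events, sx)
        frame = series.frames[0]
        background = sum(
            w * series.components[nm] for nm, w in series.background_coefficients.items()
        ) + sx.local_slope * frame.q + sx.local_intercept
        area = np.trapezoid(frame.intensity - background, frame.q)
        assert area == pytest.approx(sx.peak_area_max, rel=1e-3)

    def test_all_ejected_leaves_pure_background(self):
        cfg = replace(BASE, phi_fast=1.0, jitter_max=0.0)
        events = simulate_ejection_times(cfg)
        sx = SAXSConfig(t_max=100.0, noise_sd=0.0)
        series = synthesize_saxs_series(events, sx)
        last = series.frames[-1]
        background = sum(
            w * series.components[nm] for nm, w in series.background_coefficients.items()
        ) + sx.local_slope * last.q + sx.local_intercept
        assert np.allclose(last.intensity, background)

    def test_timestamps_follow_configured_interval(self):
        events = simulate_ejection_times(BASE)
        for interval in (2.0, 10.0):
            series = synthesize_saxs_series(events, SAXSConfig(frame_interval=interval, t_max=60.0))
            times = [f.time for f in series.frames]
            assert np.allclose(np.diff(times), interval)

    def test_bad_frame_interval_rejected(self):
        with pytest.raises(ValueError):
            SAXSConfig(frame_interval=0.0)

    def test_q_grid_must_cover_dna_window(self):
        with pytest.raises(ValueError):
            SAXSConfig(q_min=0.2)


class TestEnthalpySeries:
    def test_noise_free_v_shape_by_construction(self):
        temps = np.arange(25.0, 42.0, 2.0)
        series = synthesize_enthalpy_series(temps, 10.0)
        t_star = tstar_for_mg(10.0)
        below, above = temps < t_star, temps > t_star
        for mask in (below, above):
            assert np.allclose(np.diff(series.dH_ej[mask], 2), 0.0, atol=1e-30)
        slope_b = np.diff(series.dH_ej[below])[0]
        slope_a = np.diff(series.dH_ej[above])[0]
        assert np.sign(slope_b) != np.sign(slope_a)

    def test_default_breakpoints_10_and_20_mM(self):
        assert tstar_for_mg(10.0) == 33.0
        assert tstar_for_mg(20.0) == 37.0

    def test_50_mM_saturates_at_20_mM_value(self):
        assert tstar_for_mg(50.0) == tstar_for_mg(20.0)

    def test_sparse_side_flagged(self):
        series = synthesize_enthalpy_series([30.0, 32.0, 34.0, 36.0, 38.0], 10.0)
        assert series.sparse_side_warning  # only 2 points below T* = 33
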