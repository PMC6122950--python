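"""EMG evaluation, moment statistics and DP-curve deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq, least_squares

from ejectkin.emg import (
    EMGComponent,
    NoPeakError,
    _model_sum,
    emg_cdf,
    emg_stats,
    emg_value,
    fit_dp_curve,
    population_metrics,
)
from ejectkin.itc import DPTrace, estimate_baseline


def make_trace(t, y, meta=None):
    base = {"injection_time_s": 0.0, "temperature_C": 25.0, "mg_mM": 10.0}
    base.update(meta or {})
    return DPTrace(t, y, base)


class TestEmgValue:
    def test_left_tail_vanishes(self):
        comp = EMGComponent(a=2.0, b=3.0, c=1.5, d=10.0)
        assert emg_value(-1e3, comp) == pytest.approx(0.0, abs=1e-300)

    def test_gaussian_limit_peak(self):
        # b → 0 collapses onto a unit-area Gaussian: peak value 1/√(2π)
        comp = EMGComponent(a=1.0, b=1e-9, c=1.0, d=0.0)
        assert emg_value(0.0, comp) == pytest.approx(1 / np.sqrt(2 * np.pi), rel=1e-6)

    @pytest.mark.parametrize(
        "comp",
        [
            EMGComponent(1.0, 1.0, 1.0, 0.0),
            EMGComponent(5.0, 50.0, 2.0, 10.0),
            EMGComponent(0.3, 0.1, 8.0, -5.0),
            EMGComponent(2.0, 300.0, 0.5, 100.0),
        ],
    )
    def test_area_normalisation_vs_quadrature(self, comp):
        # adaptive-quadrature oracle: the EMG integrates to its area
        # parameter (split at the peak so quad resolves the sharp rise and
        # the long exponential tail separately)
        lo = comp.d - 12 * comp.c
        mid = comp.d + 5 * comp.c
        hi = comp.d + comp.b * 60 + 12 * comp.c
        area = sum(
            quad(lambda t: emg_value(t, comp), a, b, limit=800)[0] for a, b in [(lo, mid), (mid, hi)]
        )
        assert area == pytest.approx(comp.a, rel=1e-4)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            EMGComponent(1.0, 1.0, 0.0, 0.0)

    @given(
        b=st.floats(0.0, 100.0),
        c=st.floats(0.1, 50.0),
        d=st.floats(-50.0, 200.0),
        t=st.floats(-500.0, 1000.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_nonnegative_and_finite_everywhere(self, b, c, d, t):
        val = emg_value(t, EMGComponent(1.0, b, c, d))
        assert np.isfinite(val) and val >= 0.0


class TestEmgStats:
    def test_symmetric_gaussian_limit(self):
        s = emg_stats(EMGComponent(1.0, 0.0, 2.0, 7.0))
        assert (s.mean, s.sd, s.skewness, s.median) == (7.0, 2.0, 0.0, 7.0)

    def test_unit_parameters(self):
        # b = c = 1, d = 0: μ=1, s=√2, γ=2/2^{3/2}, median = 1 − s·γ/3 = 2/3
        s = emg_stats(EMGComponent(1.0, 1.0, 1.0, 0.0))
        assert s.mean == pytest.approx(1.0)
        assert s.sd == pytest.approx(np.sqrt(2), rel=1e-12)
        assert s.skewness == pytest.approx(2 / 2**1.5, rel=1e-12)
        assert s.median == pytest.approx(2.0 / 3.0, rel=1e-12)

    @pytest.mark.parametrize("b,c", [(0.5, 2.0), (1.0, 2.0), (2.0, 3.5), (0.2, 1.0)])
    def test_pearson_median_matches_cdf_inversion_for_moderate_skew(self, b, c):
        # the Pearson rule is an approximation; for γ < 0.5 it must sit
        # within 3 % of the exact median obtained by CDF inversion
        comp = EMGComponent(1.0, b, c, 10.0)
        stats = emg_stats(comp)
        assert stats.skewness < 0.5
        exact = brentq(lambda t: emg_cdf(t, comp) - 0.5, comp.d - 10 * c, comp.d + 10 * (b + c))
        assert stats.median == pytest.approx(exact, rel=0.03)

    @given(b=st.floats(0.0, 500.0), c=st.floats(0.1, 500.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_skewness_bounded_and_median_below_mean(self, b, c):
        s = emg_stats(EMGComponent(1.0, b, c, 0.0))
        assert 0.0 <= s.skewness < 2.0
        assert s.median <= s.mean


class TestFitDpCurve:
    def _render(self, comps, noise=0.0, dt=0.25, t_max=300.0, seed=0):
        t = np.arange(-30.0, t_max, dt)
        y = np.zeros_like(t)
        for comp in comps:
            y += emg_value(t, comp)
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, t.size)
        return make_trace(t, y)

    def test_two_well_separated_emgs_recovered_within_1pct(self):
        truth = [EMGComponent(3.0, 4.0, 2.0, 10.0), EMGComponent(2.0, 30.0, 5.0, 60.0)]
        trace = self._render(truth, noise=1e-4)
        fit = fit_dp_curve(trace, mode="bimodal")
        assert fit.mode == "bimodal"
        for got, want in zip(fit.components, truth):
            for attr in "abcd":
                assert getattr(got, attr) == pytest.approx(getattr(want, attr), rel=0.01)

    def test_flat_trace_raises_no_peak(self):
        t = np.arange(-30.0, 100.0, 0.25)
        trace = make_trace(t, np.random.default_rng(0).normal(0, 1e-4, t.size))
        with pytest.raises(NoPeakError):
            fit_dp_curve(trace)

    def test_fit_idempotence(self):
        truth = [EMGComponent(3.0, 4.0, 2.0, 10.0), EMGComponent(2.0, 30.0, 5.0, 60.0)]
        trace = self._render(truth, noise=1e-4)
        fit = fit_dp_curve(trace, mode="bimodal")
        baseline, _ = estimate_baseline(trace)
        mask = trace.time >= 0
        t, y = trace.time[mask], trace.power[mask] - baseline
        x0 = np.array([[c.a, c.b, c.c, c.d] for c in fit.components]).ravel()
        lo = [0.0, 0.1, 0.1, t[0]] * 2
        hi = [np.inf, 500.0, 500.0, t[-1]] * 2
        res = least_squares(
            lambda p: _model_sum(t, p) - y, x0, bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        assert np.allclose(res.x, x0, rtol=1e-4, atol=1e-8)

    def test_area_closure_noise_free(self):
        truth = [EMGComponent(3.0, 4.0, 2.0, 10.0), EMGComponent(2.0, 30.0, 5.0, 60.0)]
        trace = self._render(truth, noise=1e-5)
        fit = fit_dp_curve(trace, mode="bimodal")
        total = sum(c.a for c in fit.components)
        integral = np.trapezoid(trace.power[trace.time >= 0], trace.time[trace.time >= 0])
        assert total == pytest.approx(integral, rel=0.05)

    def test_median_error_decreases_with_separation(self):
        # identifiability improves monotonically across a 3-point separation grid
        errs = []
        for sep in (8.0, 16.0, 48.0):
            truth = [
                EMGComponent(3.0, 4.0, 3.0, 10.0),
                EMGComponent(3.0, 8.0, 3.0, 10.0 + sep),
            ]
            trace = self._render(truth, noise=2e-3, seed=7)
            fit = fit_dp_curve(trace, mode="bimodal")
            want = [emg_stats(c).median for c in truth]
            got = [s.median for s in fit.stats]
            errs.append(max(abs(g - w) for g, w in zip(got, want)))
        assert errs[0] >= errs[1] >= errs[2]

    def test_auto_mode_on_simulated_conditions(self, condition_results):
        # below T* the DP curve splits into two modes; above it the
        # deconvoluted peaks converge and one population suffices
        assert condition_results[(22.0, 10.0)][1].mode == "bimodal"
        assert condition_results[(32.0, 10.0)][1].mode == "bimodal"
        assert condition_results[(37.0, 10.0)][1].mode == "unimodal"
        assert condition_results[(42.0, 10.0)][1].mode == "unimodal"


class TestPopulationMetrics:
    def test_unimodal_fraction_is_one(self, condition_results):
        _, fit, metrics = condition_results[(37.0, 5.0)]
        assert fit.mode == "unimodal"
        assert metrics.fraction_fast == 1.0
        assert metrics.median_slow is None and metrics.equilibration_slow is None

    def test_equal_areas_give_half(self):
        comps = [EMGComponent(2.0, 4.0, 2.0, 10.0), EMGComponent(2.0, 30.0, 5.0, 80.0)]
        t = np.arange(-30.0, 400.0, 0.25)
        y = sum(emg_value(t, c) for c in comps) + np.random.default_rng(3).normal(0, 1e-4, t.size)
        fit = fit_dp_curve(make_trace(t, y), mode="bimodal")
        metrics = population_metrics(fit, make_trace(t, y))
        assert metrics.fraction_fast == pytest.approx(0.5, abs=0.01)

    def test_median_error_bar_is_gaussian_width(self, condition_results):
        _, fit, metrics = condition_results[(22.0, 10.0)]
        assert metrics.median_fast_se == fit.components[0].c
        assert metrics.median_slow_se == fit.components[1].c
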