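import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import logistic_curve, logistic_sdm_analytic
from qpcrcal import curve_analysis as ca
from qpcrcal.exceptions import (
    CannotEstimateError,
    NoAmplificationError,
    ShortCurveError,
    ShortWindowError,
)


def make_curve(cycles, f_raw, **kw):
    return ca.baseline_correct(np.asarray(cycles), np.asarray(f_raw), **kw)


class TestSmooth:
    def test_quadratic_reproduced_exactly(self):
        n = np.arange(30, dtype=float)
        y = 3.0 - 0.5 * n + 0.125 * n ** 2
        np.testing.assert_allclose(ca.smooth(y), y, rtol=1e-9)

    def test_constant_preserved(self):
        np.testing.assert_allclose(ca.smooth(np.full(15, 7.0)), 7.0)

    def test_noise_variance_reduced_on_sigmoid(self):
        # Monte-Carlo: smoothing must shrink scatter about the generating curve
        n = np.arange(1, 41)
        truth = logistic_curve(n)
        worse = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = truth + rng.normal(0, 10.0, size=n.size)
            if np.var(ca.smooth(noisy) - truth) >= np.var(noisy - truth):
                worse += 1
        assert worse == 0

    def test_too_short_rejected(self):
        with pytest.raises(ShortCurveError):
            ca.smooth(np.arange(4.0))


class TestSecondDerivative:
    def test_linear_gives_zero(self):
        np.testing.assert_allclose(ca.second_derivative(2.0 * np.arange(10.0)), 0.0,
                                   atol=1e-12)

    def test_quadratic_gives_constant_two(self):
        np.testing.assert_allclose(ca.second_derivative(np.arange(10.0) ** 2), 2.0)

    def test_exponential_ratio_closed_form(self):
        # d2(n)/f(n) = (E - 1)^2 / E for f = E^n under the central difference
        E = 1.9
        n = np.arange(1, 21, dtype=float)
        f = E ** n
        ratio = ca.second_derivative(f) / f[1:-1]
        np.testing.assert_allclose(ratio, (E - 1.0) ** 2 / E, rtol=1e-12)


class TestBaseline:
    def test_flat_series(self):
        c = make_curve(np.arange(1, 41), np.full(40, 100.0))
        assert c.baseline_value == pytest.approx(100.0)
        np.testing.assert_allclose(c.f_corr, 0.0, atol=1e-12)

    def test_known_generative_baseline_recovered(self):
        # exponential onset at cycle 20 over a true baseline of 50
        n = np.arange(1, 46)
        sig = np.where(n >= 20, np.minimum(1.9 ** (n - 20.0), 300.0), 0.0)
        c = make_curve(n, 50.0 + sig)
        assert c.baseline_value == pytest.approx(50.0, rel=0.01)

    def test_short_series_rejected(self):
        with pytest.raises(ShortCurveError):
            make_curve(np.arange(1, 6), np.arange(5.0))

    def test_probe_region_override(self):
        n = np.arange(1, 41)
        f = np.where(n <= 10, 80.0, 120.0)
        c = make_curve(n, f, probe_region=(3, 10))
        assert c.baseline_value == pytest.approx(80.0)


class TestLandmarks:
    @pytest.mark.parametrize("midpoint", [15.0, 20.0, 25.0, 30.0, 35.0])
    @pytest.mark.parametrize("slope", [1.0, 1.5, 2.0, 3.0])
    def test_sdm_matches_analytic_oracle(self, midpoint, slope):
        n = np.arange(1, 46)
        c = make_curve(n, 100.0 + logistic_curve(n, 1000.0, midpoint, slope))
        sdm = ca.find_sdm(c)
        assert sdm == pytest.approx(logistic_sdm_analytic(midpoint, slope), abs=0.1)

    def test_sdm_translation_equivariance(self):
        n = np.arange(1, 51)
        base = ca.find_sdm(make_curve(n, 100.0 + logistic_curve(n, 1000.0, 22.0, 1.5)))
        shifted = ca.find_sdm(make_curve(n, 100.0 + logistic_curve(n, 1000.0, 27.0, 1.5)))
        assert shifted - base == pytest.approx(5.0, abs=0.05)

    def test_flat_noise_is_no_amplification(self):
        rng = np.random.default_rng(0)
        n = np.arange(1, 41)
        with pytest.raises(NoAmplificationError):
            ca.find_sdm(make_curve(n, 100.0 + rng.normal(0, 1.0, n.size)))

    def test_takeoff_precedes_sdm_and_lower_signal(self):
        n = np.arange(1, 46)
        c = make_curve(n, 100.0 + logistic_curve(n))
        sdm = ca.find_sdm(c)
        takeoff = ca.find_takeoff(c, sdm=sdm)
        assert takeoff < sdm
        i_t = int(round(takeoff)) - 1
        i_s = int(round(sdm)) - 1
        assert c.f_smooth[i_t] < c.f_smooth[i_s]

    @staticmethod
    def _dense_takeoff_oracle(amplitude, midpoint, slope, fraction=0.2):
        # same 20%-of-d2max scan applied to the analytic second derivative
        # of the logistic on a 0.0005-cycle grid
        g = np.arange(1.0, 46.0, 0.0005)
        e = np.exp(-(g - midpoint) / slope)
        d2 = amplitude * e * (e - 1.0) / (slope ** 2 * (1.0 + e) ** 3)
        imax = int(np.argmax(d2))
        below = np.where(d2[:imax] < fraction * d2[imax])[0]
        return g[below[-1] + 1]

    @pytest.mark.parametrize("slope", [1.0, 1.5, 2.0, 3.0])
    def test_takeoff_matches_dense_analytic_oracle(self, slope):
        n = np.arange(1, 46)
        c = make_curve(n, 100.0 + logistic_curve(n, 1000.0, 25.0, slope))
        takeoff = ca.find_takeoff(c)
        oracle = self._dense_takeoff_oracle(1000.0, 25.0, slope)
        # discrete d2 (tent kernel + smoothing) reads slightly early; the
        # offset is translation-invariant and bounded by half a cycle
        assert takeoff == pytest.approx(oracle, abs=0.5)

    def test_fraction_one_approaches_sdm(self):
        n = np.arange(1, 46)
        c = make_curve(n, 100.0 + logistic_curve(n))
        sdm = ca.find_sdm(c)
        takeoff = ca.find_takeoff(c, fraction=1.0, sdm=sdm)
        assert 0 <= sdm - takeoff < 1.0


class TestSelectWindow:
    def test_arithmetic(self):
        w = ca.select_window(21.4, 26.7)
        assert (w.start, w.end, w.n_points) == (22, 26, 5)

    def test_integer_takeoff_boundary(self):
        w = ca.select_window(20.0, 24.5)
        assert w.start == 20

    def test_degenerate_raises_or_widens(self):
        with pytest.raises(ShortWindowError):
            ca.select_window(24.9, 25.1)
        # widening allowed when the smoothed signal still rises
        cycles = np.arange(1, 41)
        rising = np.arange(1, 41, dtype=float) ** 2
        w = ca.select_window(24.9, 25.1, f_smooth=rising, cycles=cycles)
        assert (w.start, w.end) == (25, 27)


class TestEfficiency:
    def test_exact_loglinear_recovery(self):
        n = np.arange(1, 41)
        f = 0.001 * 1.9 ** n.astype(float)
        curve = ca.CorrectedCurve(cycles=n, f_raw=f, f_corr=f, f_smooth=f,
                                  baseline_value=0.0, baseline_cycles=(3, 10))
        w = ca.ExponentialWindow(takeoff=19.5, sdm=26.5, start=20, end=26)
        est = ca.estimate_efficiency(curve, w)
        assert est.E == pytest.approx(1.9, abs=1e-9)
        assert est.r2 == pytest.approx(1.0, abs=1e-12)
        assert est.flags == set()

    def test_noisy_recovery_monte_carlo(self):
        # 2% multiplicative noise: E within [1.85, 1.95] in >= 95% of 500 seeds
        n = np.arange(1, 41)
        base = 0.001 * 1.9 ** n.astype(float)
        w = ca.ExponentialWindow(takeoff=19.5, sdm=26.5, start=20, end=26)
        hits = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            f = base * (1.0 + rng.normal(0, 0.02, n.size))
            curve = ca.CorrectedCurve(cycles=n, f_raw=f, f_corr=f, f_smooth=f,
                                      baseline_value=0.0, baseline_cycles=(3, 10))
            est = ca.estimate_efficiency(curve, w)
            hits += 1.85 <= est.E <= 1.95
        assert hits >= 475

    def test_nonpositive_cycles_dropped(self):
        n = np.arange(1, 41)
        f = 0.001 * 1.9 ** n.astype(float)
        f[21] = 0.0  # cycle 22 unusable
        curve = ca.CorrectedCurve(cycles=n, f_raw=f, f_corr=f, f_smooth=f,
                                  baseline_value=0.0, baseline_cycles=(3, 10))
        w = ca.ExponentialWindow(takeoff=19.5, sdm=26.5, start=20, end=26)
        est = ca.estimate_efficiency(curve, w)
        assert est.n_used == 6
        assert est.E == pytest.approx(1.9, abs=1e-9)

    def test_too_few_positive_points(self):
        n = np.arange(1, 41)
        f = np.full(40, -1.0)
        f[19:21] = [1.0, 2.0]
        curve = ca.CorrectedCurve(cycles=n, f_raw=f, f_corr=f, f_smooth=f,
                                  baseline_value=0.0, baseline_cycles=(3, 10))
        w = ca.ExponentialWindow(takeoff=19.5, sdm=26.5, start=20, end=26)
        with pytest.raises(CannotEstimateError):
            ca.estimate_efficiency(curve, w)

    def test_out_of_range_flagged_not_clamped(self):
        n = np.arange(1, 41)
        f = 0.001 * 2.5 ** n.astype(float)
        curve = ca.CorrectedCurve(cycles=n, f_raw=f, f_corr=f, f_smooth=f,
                                  baseline_value=0.0, baseline_cycles=(3, 10))
        w = ca.ExponentialWindow(takeoff=19.5, sdm=26.5, start=20, end=26)
        est = ca.estimate_efficiency(curve, w)
        assert est.E == pytest.approx(2.5, rel=1e-9)
        assert "e_out_of_range" in est.flags


class TestInvariances:
    """Noiseless landmark/efficiency invariances on the full analysis path."""

    def _analyze(self, f_raw):
        n = np.arange(1, len(f_raw) + 1)
        return ca.analyze_curve(n, f_raw)

    def _ideal(self, onset_scale=1e-4, baseline=100.0, n_cycles=45, plateau=4000.0):
        n = np.arange(1, n_cycles + 1)
        return baseline + np.minimum(onset_scale * 1.9 ** n, plateau)

    def test_translation_equivariance_full_path(self):
        f1 = self._ideal(onset_scale=1e-4)
        f2 = self._ideal(onset_scale=1e-4 / 1.9 ** 3)  # same curve 3 cycles later
        _, w1, e1 = self._analyze(f1)
        _, w2, e2 = self._analyze(f2)
        assert w2.takeoff - w1.takeoff == pytest.approx(3.0, abs=0.05)
        assert w2.sdm - w1.sdm == pytest.approx(3.0, abs=0.05)
        assert e2.E == pytest.approx(e1.E, abs=1e-6)

    @given(st.floats(min_value=0.05, max_value=50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance_full_path(self, c):
        f = self._ideal()
        _, w1, e1 = self._analyze(f)
        # scaling the whole trace (baseline included) must change nothing
        _, w2, e2 = self._analyze(f * c)
        assert w2.takeoff == pytest.approx(w1.takeoff, abs=1e-6)
        assert w2.sdm == pytest.approx(w1.sdm, abs=1e-6)
        assert (w2.start, w2.end) == (w1.start, w1.end)
        assert e2.E == pytest.approx(e1.E, rel=1e-9)


class TestEfficiencyErrorPct:
    @pytest.mark.parametrize("E, n, truncated", [
        (1.97, 30, 57),    # near-perfect efficiency, 30 cycles
        (1.90, 30, 365),   # 5% efficiency shortfall compounds dramatically
    ])
    def test_reported_percent_errors(self, E, n, truncated):
        assert int(ca.efficiency_error_pct(E, n)) == truncated

    def test_perfect_doubling_is_zero(self):
        for n in (0, 1, 30, 45):
            assert ca.efficiency_error_pct(2.0, n) == pytest.approx(0.0, abs=1e-9)
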