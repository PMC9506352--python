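"""Tests of the Ca2+-signature metric extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pawcal.calibration import CalciumTrace
from pawcal.signatures import (
    Epoch,
    baseline,
    compute_metrics,
    integrate,
    onset_delay,
    peak,
    rise_slope,
    two_dose_analysis,
)
from pawcal.synthetic import CaKinetics, make_ca_trajectory, transient_peak_time

GRID = np.arange(0.0, 2000.0 + 1e-9, 5.0)
EPOCH = Epoch("dose1", start=100.0, end=2000.0)


def _trace(ca_values, times=GRID):
    return CalciumTrace("w", times, np.asarray(ca_values, dtype=float))


def _flat(value=1e-7):
    return _trace(np.full_like(GRID, value))


class TestBaseline:
    def test_flat(self):
        assert baseline(_flat(), EPOCH) == pytest.approx(1e-7)

    def test_uses_only_pre_stimulus_samples(self):
        ca = np.full_like(GRID, 1e-7)
        ca[GRID >= 100.0] = 9e-7  # post-stimulus values must not leak in
        assert baseline(_trace(ca), EPOCH) == pytest.approx(1e-7)

    def test_linear_ramp_gives_midpoint(self):
        # ramp 1e-7 -> 2e-7 across the 60 s pre-stimulus window
        ca = np.full_like(GRID, 1e-7)
        win = (GRID >= 40.0) & (GRID < 100.0)
        ca[win] = np.linspace(1e-7, 2e-7, win.sum())
        half_step = 0.5e-7 / win.sum()
        assert baseline(_trace(ca), EPOCH) == pytest.approx(1.5e-7, abs=2 * half_step)


class TestPeak:
    def test_matches_closed_form_argmax(self):
        kin = CaKinetics(rise_tau=10.0, decay_tau=120.0, transient_amplitude=5e-7)
        tr = make_ca_trajectory(kin, GRID)
        _, t_peak = peak(tr, EPOCH)
        assert abs(t_peak - transient_peak_time(kin)) <= 5.0

    def test_flat_trace_tie_breaks_to_start(self):
        pk, t = peak(_flat(), EPOCH)
        assert pk == pytest.approx(1e-7)
        assert t == EPOCH.start

    def test_equal_maxima_earlier_wins(self):
        ca = np.full_like(GRID, 1e-7)
        ca[GRID == 200.0] = 5e-7
        ca[GRID == 700.0] = 5e-7
        _, t = peak(_trace(ca), EPOCH)
        assert t == 200.0


class TestOnsetDelay:
    def _noisy_baseline(self, rng, sd=2e-9):
        ca = np.full_like(GRID, 1e-7)
        ca[GRID < 100.0] += rng.normal(0, sd, size=(GRID < 100.0).sum())
        return ca

    def test_step_at_stimulus(self):
        rng = np.random.default_rng(0)
        ca = self._noisy_baseline(rng)
        ca[GRID > 100.0] = 5e-7  # effect visible from the first post-stimulus sample
        delay, flags = onset_delay(_trace(ca), EPOCH)
        assert delay == 5.0
        assert "onset_censored" not in flags

    def test_no_response_censored(self):
        rng = np.random.default_rng(1)
        delay, flags = onset_delay(_trace(self._noisy_baseline(rng)), EPOCH)
        assert delay == EPOCH.end - EPOCH.start
        assert "onset_censored" in flags

    def test_single_sample_spike_not_onset(self):
        rng = np.random.default_rng(2)
        ca = self._noisy_baseline(rng)
        ca[GRID == 300.0] = 5e-7  # persistence rule requires 2 consecutive samples
        delay, flags = onset_delay(_trace(ca), EPOCH)
        assert "onset_censored" in flags

    def test_slow_rise_crossing_matches_analytic(self):
        """Deterministic sustained rise with known baseline noise sd: the
        threshold crossing time solves S(1-exp(-t/tau)) = 3*sd."""
        sd = 2e-9
        rng = np.random.default_rng(3)
        ca = self._noisy_baseline(rng, sd)
        S, tau = 3e-7, 300.0
        post = GRID > 100.0
        ca[post] = 1e-7 + S * (1 - np.exp(-(GRID[post] - 100.0) / tau))
        tr = _trace(ca)
        base = baseline(tr, EPOCH)
        from pawcal.signatures import pre_stimulus_sd

        sd_hat = pre_stimulus_sd(tr, EPOCH)
        excess = base + 3 * sd_hat - 1e-7
        t_cross = -tau * np.log(1 - excess / S)
        delay, flags = onset_delay(tr, EPOCH)
        assert "onset_censored" not in flags
        assert delay == pytest.approx(t_cross, abs=5.0)

    def test_zero_variance_falls_back_to_relative_threshold(self):
        ca = np.full_like(GRID, 1e-7)
        ca[GRID > 100.0] = 2e-7
        delay, flags = onset_delay(_trace(ca), EPOCH)
        assert "relative_onset_threshold" in flags
        assert delay == 5.0


class TestRiseSlope:
    def test_exact_on_linear_rise(self):
        rng = np.random.default_rng(4)
        ca = np.full_like(GRID, 1e-7)
        ca[GRID < 100.0] += rng.normal(0, 1e-10, size=(GRID < 100.0).sum())
        rise = (GRID > 100.0) & (GRID <= 400.0)
        b = 1e-9  # M/s
        ca[rise] = 1e-7 + b * (GRID[rise] - 100.0)
        ca[GRID > 400.0] = ca[rise][-1]
        assert rise_slope(_trace(ca), EPOCH) == pytest.approx(b, rel=1e-3)

    def test_flat_trace_slope_zero(self):
        assert rise_slope(_flat(), EPOCH) == 0.0

    def test_ols_sampling_distribution(self):
        """Noisy linear rise: slope estimator is unbiased with the closed-form
        OLS standard deviation."""
        rng = np.random.default_rng(5)
        n, sigma, b = 20, 5e-9, 2e-9
        t = np.arange(n) * 5.0
        sd_closed = sigma / np.sqrt(np.sum((t - t.mean()) ** 2))
        slopes = []
        for _ in range(400):
            y = 1e-7 + b * t + rng.normal(0, sigma, n)
            slopes.append(np.polyfit(t, y, 1)[0])
        slopes = np.asarray(slopes)
        assert slopes.mean() == pytest.approx(b, abs=3 * sd_closed / np.sqrt(400))
        assert slopes.std(ddof=1) == pytest.approx(sd_closed, rel=0.2)


class TestIntegrate:
    def test_rectangle(self):
        assert integrate(_flat(), EPOCH, 1800.0) == pytest.approx(1.8e-4, rel=1e-12)

    def test_triangle_bump(self):
        base, h = 1e-9, 4e-7
        ca = np.full_like(GRID, base)
        up = (GRID >= 200.0) & (GRID <= 400.0)
        ca[up] = base + h * (1 - np.abs(GRID[up] - 300.0) / 100.0)
        total = integrate(_trace(ca), EPOCH, 1800.0)
        assert total - base * 1800.0 == pytest.approx(h * 200.0 / 2, rel=1e-9)

    def test_double_exponential_closed_form(self):
        kin = CaKinetics(rise_tau=10.0, decay_tau=120.0, transient_amplitude=5e-7,
                         baseline=5e-8)
        tr = make_ca_trajectory(kin, GRID)
        W = 1800.0
        r, d = kin.rise_tau, kin.decay_tau
        tstar = np.log(d / r) * r * d / (d - r)
        norm = 1.0 / (np.exp(-tstar / d) - np.exp(-tstar / r))
        analytic = kin.baseline * W + kin.transient_amplitude * norm * (
            d * (1 - np.exp(-W / d)) - r * (1 - np.exp(-W / r))
        )
        assert integrate(tr, EPOCH, W) == pytest.approx(analytic, rel=1e-3)

    def test_window_truncated_by_epoch_end(self):
        short = Epoch("e", 100.0, 400.0)
        assert integrate(_flat(), short, 1800.0) == pytest.approx(1e-7 * 300.0)

    def test_additivity_on_shared_grid(self):
        tr = make_ca_trajectory(CaKinetics(), GRID)
        whole = integrate(tr, Epoch("w", 100.0, 1900.0), 1800.0)
        left = integrate(tr, Epoch("l", 100.0, 1000.0), 900.0)
        right = integrate(tr, Epoch("r", 1000.0, 1900.0), 900.0)
        assert whole == pytest.approx(left + right, rel=1e-12)


class TestScaleEquivariance:
    @settings(deadline=None, max_examples=20)
    @given(c=st.floats(0.1, 50.0))
    def test_scaling_trace_scales_metrics(self, c):
        rng = np.random.default_rng(6)
        ca = np.full_like(GRID, 1e-7)
        ca[GRID < 100.0] += rng.normal(0, 2e-9, size=(GRID < 100.0).sum())
        post = GRID > 100.0
        ca[post] += 4e-7 * (1 - np.exp(-(GRID[post] - 100.0) / 120.0))
        m1 = compute_metrics(_trace(ca), EPOCH, 1800.0)
        m2 = compute_metrics(_trace(ca * c), EPOCH, 1800.0)
        assert m2.peak_ca == pytest.approx(c * m1.peak_ca, rel=1e-9)
        assert m2.auc == pytest.approx(c * m1.auc, rel=1e-9)
        assert m2.rise_slope == pytest.approx(c * m1.rise_slope, rel=1e-6)
        assert m2.peak_time == m1.peak_time
        assert m2.onset_delay == m1.onset_delay


class TestTwoDose:
    def _double_response(self, amp2_over_amp1=1.0):
        rng = np.random.default_rng(7)
        ca = np.full_like(GRID, 1e-7)
        ca[GRID < 100.0] += rng.normal(0, 1e-9, size=(GRID < 100.0).sum())
        for start, amp in ((100.0, 2e-7), (1000.0, 2e-7 * amp2_over_amp1)):
            seg = (GRID > start) & (GRID <= start + 600.0)
            dt = GRID[seg] - start
            ca[seg] += amp * (np.exp(-dt / 120.0) - np.exp(-dt / 15.0)) / 0.67
        return _trace(ca)

    def test_identical_doses_give_matching_metrics(self):
        metrics = two_dose_analysis(self._double_response(), [100.0, 1000.0], 600.0)
        m1, m2 = metrics
        assert m2.peak_ca == pytest.approx(m1.peak_ca, rel=0.05)
        assert m2.auc == pytest.approx(m1.auc, rel=0.05)

    def test_double_amplitude_second_dose(self):
        m1, m2 = two_dose_analysis(self._double_response(2.0), [100.0, 1000.0], 600.0)
        assert (m2.peak_ca - m2.baseline_ca) / (m1.peak_ca - m1.baseline_ca) == (
            pytest.approx(2.0, rel=0.05)
        )

    def test_epochs_do_not_overlap(self):
        metrics = two_dose_analysis(self._double_response(), [100.0, 400.0], 1800.0)
        assert metrics[0].window <= 300.0
        assert len(metrics) == 2

    def test_unsorted_dose_times_rejected(self):
        with pytest.raises(ValueError):
            two_dose_analysis(self._double_response(), [1000.0, 100.0], 600.0)
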