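"""Truncated-exponential MLE, bleach correction, bootstrap, model selection."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import replikinetics as rk
from replikinetics.dwell import TrackDurationSample, TwoExpFit, _two_exp_nll, bca_interval
from replikinetics.errors import (
    ConfigurationError,
    FitError,
    InputError,
    InsufficientDataError,
    UninformativeEstimateError,
)


def sample_of(durations, L, interval=1.0, exposure=0.5):
    return TrackDurationSample(
        np.asarray(durations, dtype=float), L,
        rk.AcquisitionSettings(exposure, interval))


class TestTruncatedExponentialMle:
    def test_closed_form_examples(self):
        fit = rk.fit_truncated_exponential(sample_of([3, 4, 8], 2))
        assert fit.tau == pytest.approx(3.0)
        fit = rk.fit_truncated_exponential(sample_of([7], 4))
        assert fit.tau == pytest.approx(3.0)

    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=60),
           st.floats(0.0, 5.0))
    def test_mle_equals_mean_minus_L(self, shifted, L):
        durations = L + np.asarray(shifted)
        fit = rk.fit_truncated_exponential(sample_of(durations, L))
        assert fit.tau == pytest.approx(durations.mean() - L, rel=1e-12, abs=1e-12)
        assert fit.ci95[0] <= fit.tau <= fit.ci95[1]

    def test_simulation_recovery(self):
        rng = np.random.default_rng(61)
        durations = 4.0 + rng.exponential(10.0, 10_000)
        fit = rk.fit_truncated_exponential(sample_of(durations, 4.0))
        assert abs(fit.tau - 10.0) < 3 * 10.0 / np.sqrt(10_000)

    def test_input_validation(self):
        with pytest.raises(InputError):
            rk.fit_truncated_exponential(sample_of([], 0))
        with pytest.raises(InputError):
            sample_of([1.0, 5.0], 2.0)  # duration below L
        with pytest.raises(FitError):
            rk.fit_truncated_exponential(sample_of([2.0, 2.0], 2.0))

    def test_frame_correction_recovers_geometric_rate(self):
        # frame counts are geometric; the corrected tau is the exact inverse
        interval, tau = 1.0, 7.5
        q = math.exp(-interval / tau)
        mean_minus_L = interval * q / (1 - q)
        assert rk.frame_corrected_tau(mean_minus_L, interval) == pytest.approx(tau)


class TestBleachCorrection:
    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4))
    def test_rate_sum_roundtrip(self, t_bound, t_bleach):
        # composing rates then inverting reproduces the correction formula
        t_track = 1.0 / (1.0 / t_bound + 1.0 / t_bleach)
        assert rk.correct_bound_time(t_track, t_bleach) == pytest.approx(
            t_bound, rel=1e-9)

    @pytest.mark.parametrize("t_track, t_bleach, expected",
                             [(5, 10, 10), (10, 30, 15), (2, 1000, 2.004008)])
    def test_correction_examples(self, t_track, t_bleach, expected):
        assert rk.correct_bound_time(t_track, t_bleach) == pytest.approx(
            expected, rel=1e-4)

    def test_unidentifiable_raises(self):
        with pytest.raises(UninformativeEstimateError):
            rk.correct_bound_time(10.0, 10.0)
        with pytest.raises(UninformativeEstimateError):
            rk.correct_bound_time(12.0, 10.0)

    def test_calibration_arithmetic(self):
        # fitted tau of 20 s at continuous 0.5 s exposure
        rng = np.random.default_rng(62)
        control = TrackDurationSample(
            2.0 + rng.exponential(20.0, 5000), 2.0,
            rk.AcquisitionSettings(0.5, 0.5))
        cal = rk.calibrate_bleach(control, frame_correction=False)
        assert cal.t_constant == pytest.approx(control.durations.mean() - 2.0)
        # identity at interval == exposure, 10x at 5 s intervals
        assert cal.bleach_time(rk.AcquisitionSettings(0.5, 0.5)) == pytest.approx(
            cal.t_constant)
        assert cal.bleach_time(rk.AcquisitionSettings(0.5, 5.0)) == pytest.approx(
            10 * cal.t_constant)

    def test_calibration_recovers_generator_truth(self, bleach_calibration):
        se = 15.0 / np.sqrt(bleach_calibration.control.n)
        assert abs(bleach_calibration.t_constant - 15.0) < 3 * se


class TestBootstrap:
    def test_identical_durations_zero_width_ci(self):
        sample = sample_of([6.0] * 40, 4.0)
        cal = rk.BleachCalibration(t_constant=30.0)
        est = rk.bootstrap_estimate(sample, cal, n_boot=500, seed=1)
        assert est.ci95[0] == pytest.approx(est.ci95[1])
        assert est.se == pytest.approx(0.0, abs=1e-12)

    def test_seed_reproducibility(self, bleach_calibration, spt_settings):
        p = rk.TrackSimParams(true_bound_time=10.0, n_molecules=200, seed=63)
        sample = rk.gen_track_durations(p, spt_settings)
        a = rk.bootstrap_estimate(sample, bleach_calibration, n_boot=500, seed=9)
        b = rk.bootstrap_estimate(sample, bleach_calibration, n_boot=500, seed=9)
        assert a.ci95 == b.ci95 and a.se == b.se

    def test_small_n_boot_rejected(self, bleach_calibration):
        sample = sample_of([5, 6, 7], 4.0)
        with pytest.raises(ConfigurationError):
            rk.bootstrap_estimate(sample, bleach_calibration, n_boot=50)

    def test_bca_matches_scipy_reference(self):
        # independent route: scipy's BCa on the same statistic and data
        rng = np.random.default_rng(64)
        data = rng.exponential(10.0, 120)
        theta = data.mean()
        idx = rng.integers(0, data.size, size=(4000, data.size))
        boot = data[idx].mean(axis=1)
        jack = (data.sum() - data) / (data.size - 1)
        lo, hi = bca_interval(boot, theta, jack)
        ref = stats.bootstrap((data,), np.mean, n_resamples=4000,
                              method="BCa", random_state=65)
        assert lo == pytest.approx(ref.confidence_interval.low, rel=0.03)
        assert hi == pytest.approx(ref.confidence_interval.high, rel=0.03)


class TestConstrainedFit:
    def _dataset(self, t_bound, seed, settings, n=120):
        p = rk.TrackSimParams(true_bound_time=t_bound,
                              constant_exposure_bleach_time=15.0,
                              n_molecules=n, seed=seed)
        sample = rk.gen_track_durations(p, settings)
        ctrl = rk.gen_bleach_control(
            rk.TrackSimParams(true_bound_time=np.inf,
                              constant_exposure_bleach_time=15.0,
                              n_molecules=400, seed=seed + 1),
            rk.AcquisitionSettings(0.5, 0.5), min_localizations=4)
        return sample, rk.calibrate_bleach(ctrl)

    def test_interior_truth_gives_interior_estimate(self):
        settings = rk.AcquisitionSettings(2.0, 10.0)
        # truth equal to the bleach time (75 s here): identifiable interior
        sample, cal = self._dataset(75.0, 66, settings, n=400)
        est = rk.constrained_fit(sample, cal)
        assert not est.diagnostics["at_lower_bound"]
        assert not est.diagnostics["at_upper_bound"]
        assert 20 < est.t_bound < 400

    def test_pure_bleaching_flags_upper_bound(self):
        settings = rk.AcquisitionSettings(2.0, 10.0)
        sample, cal = self._dataset(np.inf, 67, settings, n=400)
        est = rk.constrained_fit(sample, cal)
        assert est.diagnostics["at_upper_bound"]

    def test_bleach_estimate_within_allowed_variation(self):
        settings = rk.AcquisitionSettings(2.0, 10.0)
        sample, cal = self._dataset(300.0, 68, settings, n=200)
        est = rk.constrained_fit(sample, cal, bleach_variation=0.2)
        scaled = cal.bleach_time(settings)
        assert 0.8 * scaled <= est.t_bleach <= 1.2 * scaled

    def test_user_initial_outside_bounds_rejected(self):
        settings = rk.AcquisitionSettings(2.0, 10.0)
        sample, cal = self._dataset(100.0, 69, settings)
        with pytest.raises(InputError):
            rk.constrained_fit(sample, cal, initial=9000.0)


class TestTwoExponential:
    def test_p_equal_one_recovers_single_model(self):
        rng = np.random.default_rng(71)
        sample = sample_of(4.0 + rng.exponential(8.0, 400), 4.0)
        single = rk.fit_truncated_exponential(sample)
        shifted = sample.durations - sample.truncation_point
        nll = _two_exp_nll(np.array([1.0, single.tau, 50.0]), shifted)
        assert -nll == pytest.approx(single.log_likelihood, rel=1e-12)

    def test_mixture_recovery(self):
        rng = np.random.default_rng(72)
        d = np.concatenate([4.0 + rng.exponential(3.0, 1000),
                            4.0 + rng.exponential(60.0, 1000)])
        fit = rk.fit_two_exponential(sample_of(d, 4.0))
        assert fit.tau1 == pytest.approx(3.0, abs=3 * 3.0 / np.sqrt(1000))
        assert fit.tau2 == pytest.approx(60.0, abs=3 * 60.0 / np.sqrt(1000))
        assert fit.p == pytest.approx(0.5, abs=0.1)
        assert fit.llr_p_value < 1e-6

    def test_single_population_degenerates_gracefully(self):
        rng = np.random.default_rng(73)
        sample = sample_of(4.0 + rng.exponential(10.0, 500), 4.0)
        fit = rk.fit_two_exponential(sample)
        # implied mean matches the sample regardless of the split
        implied = fit.p * fit.tau1 + (1 - fit.p) * fit.tau2
        assert implied == pytest.approx(sample.durations.mean() - 4.0, rel=0.15)

    def test_bound_time_components_from_calibration(self):
        rng = np.random.default_rng(74)
        d = np.concatenate([4.0 + rng.exponential(3.0, 800),
                            4.0 + rng.exponential(20.0, 800)])
        cal = rk.BleachCalibration(t_constant=15.0)
        sample = sample_of(d, 4.0)  # interval 1, exposure 0.5 -> T_bleach 30
        fit = rk.fit_two_exponential(sample, cal)
        # 1/tau = 1/T_bleach + 1/T_bound inverted per component
        assert fit.t_bound_alpha == pytest.approx(
            fit.tau1 * 30 / (30 - fit.tau1), rel=1e-9)

    def test_selection_requires_all_criteria(self):
        single = rk.ExponentialFit(tau=10.0, se=1.0, ci95=(8, 12),
                                   log_likelihood=-100.0, n=100)
        good = TwoExpFit(p=0.5, tau1=3, tau2=60, t_bound_alpha=None,
                         t_bound_beta=None, log_likelihood=-80.0,
                         bic=3 * np.log(100) + 160.0, llr_p_value=1e-6,
                         n=100, on_bounds=False, timescale_bounds=(0.1, 5400))
        assert rk.select_model(single, good).choice == "two"
        pegged = TwoExpFit(p=0.5, tau1=3, tau2=5400, t_bound_alpha=None,
                           t_bound_beta=None, log_likelihood=-80.0,
                           bic=good.bic, llr_p_value=1e-6, n=100,
                           on_bounds=True, timescale_bounds=(0.1, 5400))
        decision = rk.select_model(single, pegged)
        assert decision.choice == "single"
        assert any("bound" in r for r in decision.reasons)


class TestWeightedAverage:
    def _est(self, value, se, n=100):
        return rk.BoundTimeEstimate(t_track=value / 2, t_bleach=value,
                                    t_bound=value, se=se, n=n)

    def test_equal_ses_arithmetic_mean(self):
        avg = rk.weighted_average([self._est(10, 1.0), self._est(20, 1.0)])
        assert avg.t_bound == pytest.approx(15.0)

    def test_inverse_variance_weights(self):
        avg = rk.weighted_average([self._est(10, 1.0), self._est(20, 2.0)])
        assert avg.t_bound == pytest.approx(12.0)
        assert avg.se == pytest.approx(np.sqrt(1 / (1 + 0.25)))

    def test_single_estimate_unchanged(self):
        e = self._est(10, 1.0)
        assert rk.weighted_average([e]) is e

    def test_missing_se_falls_back_to_n_weighting(self):
        with pytest.warns(UserWarning):
            avg = rk.weighted_average(
                [self._est(10, None, n=100), self._est(20, 1.0, n=300)])
        assert avg.t_bound == pytest.approx(17.5)


class TestBlinking:
    def test_gap_constant_recovery(self):
        rng = np.random.default_rng(75)
        gaps = rng.exponential(0.4, 20_000)
        model = rk.analyze_blinking(gaps, exposure=0.5)
        n_obs = np.sum((gaps >= 0.5) & (gaps <= 2.6))
        assert model.gap_time_constant == pytest.approx(
            0.4, abs=3 * 0.4 / np.sqrt(n_obs))

    def test_all_gaps_above_cutoff_raise(self):
        with pytest.raises(InsufficientDataError):
            rk.analyze_blinking(np.array([3.0, 4.0, 5.0]), exposure=0.5)

    def test_termination_probability_formula(self):
        model = rk.BlinkModel(gap_time_constant=0.386, blink_fraction=1.0)
        p = rk.premature_termination_probability(model, interval=1.0, memory=1)
        assert p == pytest.approx(np.exp(-1.0 / 0.386), rel=1e-9)
        assert p == pytest.approx(0.075, abs=0.005)

    def test_termination_monotone_in_interval(self):
        model = rk.BlinkModel(gap_time_constant=0.386, blink_fraction=0.49)
        p1 = rk.premature_termination_probability(model, 1.0)
        p2 = rk.premature_termination_probability(model, 2.0)
        p5 = rk.premature_termination_probability(model, 5.0)
        assert p5 < p2 < p1
        assert rk.premature_termination_probability(model, np.inf) == 0.0


class TestEstimatorBiasWithoutTruncation:
    def test_ignoring_truncation_biases_tau_upward(self):
        # fitting truncated data as if untruncated inflates the mean time
        rng = np.random.default_rng(76)
        durations = 4.0 + rng.exponential(10.0, 5000)
        naive = durations.mean()  # no truncation correction
        corrected = rk.fit_truncated_exponential(sample_of(durations, 4.0)).tau
        assert naive > corrected + 3.0
        assert corrected == pytest.approx(10.0, abs=3 * 10 / np.sqrt(5000))
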