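import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import vonmises

from crowdtrack.metrics import (LineFit, PerceptualError, cosine_similarity,
                                crowding_extent_continuous,
                                crowding_extent_trial_based,
                                estimate_extent_continuous,
                                fit_error_vs_distance, fit_exponential_decay,
                                perceptual_error_vonmises, recovery_time)
from crowdtrack.preprocessing import PostJumpWindows


class TestCosineSimilarity:
    def test_identity_is_one(self, rng):
        theta = rng.uniform(0, 360, 1000)
        assert cosine_similarity(theta, theta) == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_is_minus_one(self, rng):
        theta = rng.uniform(0, 360, 500)
        assert cosine_similarity(theta, (theta + 180) % 360) == pytest.approx(-1.0)

    def test_equals_mean_cos_error(self, rng):
        """The printed sum form reduces to the mean cosine of the report error."""
        s = rng.uniform(0, 360, 1000)
        r = rng.uniform(0, 360, 1000)
        expected = np.mean(np.cos(np.radians(s - r)))
        assert cosine_similarity(s, r) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-180, 180))
    def test_invariant_to_common_rotation(self, shift):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 360, 200)
        r = rng.uniform(0, 360, 200)
        assert cosine_similarity((s + shift) % 360, (r + shift) % 360) == \
            pytest.approx(cosine_similarity(s, r), abs=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([], [])


class TestLineFits:
    def test_exactly_linear_data(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        fit = fit_error_vs_distance(3.0 * x + 2.0, x)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(2.0)

    def test_matches_hand_computed_normal_equations(self):
        # 5 points; slope = 19/10, intercept = 4.6 - 1.9*2 computed by hand
        x = np.array([0, 1, 2, 3, 4], dtype=float)
        y = np.array([1, 3, 4, 6, 9], dtype=float)
        fit = fit_error_vs_distance(y, x)
        assert fit.slope == pytest.approx(1.9, abs=1e-12)
        assert fit.intercept == pytest.approx(0.8, abs=1e-12)

    def test_flat_noise_gives_near_zero_slope(self, rng):
        x = np.tile(np.linspace(0, 5, 100), 50)
        y = rng.normal(8.0, 1.0, x.size)
        fit = fit_error_vs_distance(y, x)
        assert abs(fit.slope) < 3 * 1.0 / (np.sqrt(x.size) * x.std())

    def test_constant_distance_rejected(self):
        with pytest.raises(ValueError):
            fit_error_vs_distance([1.0, 2.0], [3.0, 3.0])


class TestContinuousExtent:
    def test_hand_computed_intersection(self):
        est = crowding_extent_continuous(LineFit(-2.0, 12.0), LineFit(0.0, 2.0), 10.0)
        assert est.extent_deg == pytest.approx(5.0)
        assert est.raw_extent_deg == pytest.approx(5.0)

    def test_parallel_lines_rejected(self):
        with pytest.raises(ValueError, match="parallel"):
            crowding_extent_continuous(LineFit(1.0, 0.0), LineFit(1.0, 5.0), 10.0)

    def test_clipping_retains_raw_value(self):
        est = crowding_extent_continuous(LineFit(-2.0, 30.0), LineFit(0.0, 2.0), 5.0)
        assert est.extent_deg == 5.0
        assert est.raw_extent_deg == pytest.approx(14.0)

    def test_recovers_hinge_from_synthetic_series(self, rng):
        """Hinged noisy data: the iterated estimator finds the true hinge."""
        e_c, base, slope = 3.0, 8.0, 5.0
        d = np.tile(np.linspace(0, 5, 2000), 4)
        fl = base + slope * np.maximum(0, e_c - d) + rng.normal(0, 2.0, d.size)
        iso = base + rng.normal(0, 2.0, d.size)
        est = estimate_extent_continuous(fl, d, iso, d, 5.0)
        assert abs(est.extent_deg - e_c) < 0.3
        plain = estimate_extent_continuous(fl, d, iso, d, 5.0, refine=False)
        assert plain.extent_deg > est.extent_deg  # single pass overshoots


class TestVonMises:
    def test_zero_errors_give_zero_sd(self):
        pe = perceptual_error_vonmises(np.zeros(50))
        assert pe.circular_sd_deg == 0.0
        assert np.isinf(pe.kappa)

    def test_kappa_recovered_within_5_percent(self):
        draws = np.degrees(vonmises.rvs(4.0, size=10_000,
                                        random_state=np.random.default_rng(1)))
        pe = perceptual_error_vonmises(draws)
        assert abs(pe.kappa - 4.0) / 4.0 < 0.05

    def test_sd_decreasing_in_concentration(self):
        sds = []
        for kappa in (1.0, 2.0, 4.0, 8.0):
            draws = np.degrees(vonmises.rvs(kappa, size=5000,
                                            random_state=np.random.default_rng(2)))
            sds.append(perceptual_error_vonmises(draws).circular_sd_deg)
        assert all(a > b for a, b in zip(sds, sds[1:]))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            perceptual_error_vonmises([1.0, 2.0, 3.0])


def _pe(d, sd):
    return PerceptualError(d, sd, 1.0, 100)


class TestTrialBasedExtent:
    def test_hand_computed_hinge(self):
        pts = [_pe(d, 30.0 - 5.0 * d) for d in (0.0, 1.0, 2.0, 3.0)]
        est = crowding_extent_trial_based(pts, _pe(None, 5.0), 5.0)
        assert est.extent_deg == pytest.approx(5.0)

    def test_line_equal_to_baseline_flagged_zero(self):
        pts = [_pe(d, 5.0) for d in (0.0, 1.0, 2.0)]
        est = crowding_extent_trial_based(pts, _pe(None, 5.0), 5.0)
        assert est.extent_deg == 0.0
        assert est.flag is not None

    def test_never_meeting_baseline_flagged_at_max(self):
        pts = [_pe(d, 6.0 + 0.0001 * d) for d in (0.0, 1.0, 2.0)]
        est = crowding_extent_trial_based(pts, _pe(None, 5.0), 5.0, refine=False)
        assert est.extent_deg == 5.0
        assert est.flag is not None

    def test_recovers_interior_hinge_with_refinement(self):
        dists = (0.0, 0.31, 0.35, 1.35, 2.2, 3.37, 5.0)
        pts = [_pe(d, 10.0 + 8.0 * max(0.0, 2.0 - d)) for d in dists]
        est = crowding_extent_trial_based(pts, _pe(None, 10.0), 5.0)
        assert est.extent_deg == pytest.approx(2.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            crowding_extent_trial_based([_pe(0, 10), _pe(1, 8)], _pe(None, 5), 5.0)


class TestDecayFit:
    def test_noiseless_parameters_recovered(self):
        dt = 1.0 / 144
        t = np.arange(300) * dt
        y = 40.0 * np.exp(-3.0 * t) + 8.0
        fit = fit_exponential_decay(y, dt)
        assert fit.a_deg == pytest.approx(40.0, rel=1e-6)
        assert fit.b_per_s == pytest.approx(3.0, rel=1e-6)
        assert fit.c_deg == pytest.approx(8.0, rel=1e-6)
        assert fit.rmse_deg < 1e-8

    def test_constant_input_degenerates_gracefully(self):
        fit = fit_exponential_decay(np.full(100, 6.0), 1.0 / 144)
        assert fit.a_deg == pytest.approx(0.0, abs=1e-6)
        assert fit.c_deg == pytest.approx(6.0, abs=1e-6)

    def test_motor_corrected_drops_latency_plateau(self):
        """A delay plateau before the decay biases b down; skipping it helps."""
        dt = 1.0 / 144
        t = np.arange(300) * dt
        y = np.where(t < 40 * dt, 50.0, 42.0 * np.exp(-3.5 * (t - 40 * dt)) + 8.0)
        plain = fit_exponential_decay(y, dt, motor_corrected=False)
        corr = fit_exponential_decay(y, dt, motor_corrected=True)
        assert abs(corr.b_per_s - 3.5) < abs(plain.b_per_s - 3.5)
        assert corr.b_per_s == pytest.approx(3.5, rel=1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_decay(np.ones(5), 1.0 / 144)


class TestRecoveryTime:
    def test_constant_windows_recover_immediately(self):
        w = PostJumpWindows(np.full((10, 300), 5.0), 300, 0, 1.0 / 144)
        assert recovery_time(w).recovery_ms == 0.0

    def test_step_function_recovers_at_step(self, rng):
        k = 120
        mat = np.full((40, 300), 5.0) + rng.normal(0, 0.05, (40, 300))
        mat[:, :k] += 30.0
        w = PostJumpWindows(mat, 300, 0, 1.0 / 144)
        res = recovery_time(w)
        assert abs(res.recovery_ms - k / 144 * 1000) < 60.0

    def test_never_recovering_is_flagged(self, rng):
        # every column sits far from the pooled baseline mean (alternating
        # levels), so the scan never finds a non-significant column
        mat = np.empty((20, 300))
        mat[:, ::2], mat[:, 1::2] = 30.0, 10.0
        mat += rng.normal(0, 0.01, mat.shape)
        w = PostJumpWindows(mat, 300, 0, 1.0 / 144)
        res = recovery_time(w)
        assert res.flag is not None
        assert res.recovery_ms == pytest.approx(299 / 144 * 1000)

    def test_single_jump_rejected(self):
        with pytest.raises(ValueError):
            recovery_time(PostJumpWindows(np.zeros((1, 300)), 300, 0, 1.0 / 144))
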