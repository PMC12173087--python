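import numpy as np
import pytest

from crowdtrack.angles import signed_diff_deg
from crowdtrack.paradigm import (DECREASING, FLANKED, INCREASING, ISOLATED,
                                 ConfigError, ParadigmConfig, TrialSpec,
                                 assign_flanker_gaps, build_block_schedule,
                                 build_trial_based_schedule,
                                 distance_trajectory, draw_target_orientation,
                                 generate_continuous_trial, jump_times_for_trend,
                                 log_spaced_jump_distances)


class TestConfig:
    def test_defaults_give_5760_frames(self, default_config):
        assert default_config.n_frames == 5760

    @pytest.mark.parametrize("kwargs", [
        {"sample_rate_hz": 0}, {"trial_duration_s": -1},
        {"rotation_speed_deg_s": -1}, {"jump_distances_deg": (0.0, 1.0)},
        {"jump_distances_deg": (2.0, 1.0)}, {"n_flanked_per_block": 7},
        {"trial_based_reps": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ParadigmConfig(**kwargs)

    def test_log_spaced_helper_matches_closed_form(self):
        d = log_spaced_jump_distances()
        expected = np.geomspace(0.8, 5.8, 5) - 0.8
        np.testing.assert_allclose(d, expected)
        assert d[0] == 0.0 and np.isclose(d[-1], 5.0)


class TestOrientationDraws:
    def test_target_orientation_in_range_and_deterministic(self):
        a = draw_target_orientation(np.random.default_rng(7))
        b = draw_target_orientation(np.random.default_rng(7))
        assert 0.0 <= a < 360.0
        assert a == b

    def test_target_orientation_uniform_rayleigh(self, rng):
        """10^5 draws should not reject circular uniformity (Rayleigh test)."""
        pingouin = pytest.importorskip("pingouin")
        draws = np.array([draw_target_orientation(rng) for _ in range(10_000)])
        z, p = pingouin.circ_rayleigh(np.radians(draws))
        assert p > 0.01

    def test_gap_construction_from_known_draw(self):
        class FixedRng:
            def normal(self, loc, scale):
                return loc + 10.0
        gaps = assign_flanker_gaps(0.0, FixedRng())
        np.testing.assert_allclose(gaps, [10.0, 100.0, 190.0, 280.0])

    def test_gaps_at_90_degree_intervals(self, rng):
        for _ in range(20):
            target = rng.uniform(0, 360)
            gaps = assign_flanker_gaps(target, rng)
            assert np.all((gaps >= 0) & (gaps < 360))
            diffs = signed_diff_deg(np.roll(gaps, -1), gaps) % 360
            np.testing.assert_allclose(diffs, 90.0)

    def test_gap_circular_sd_matches_generating_sd(self, rng):
        """Circular SD of gap1 about the target ~ 45 deg (wrapped normal)."""
        from scipy.stats import circstd
        draws = np.array([assign_flanker_gaps(180.0, rng)[0] for _ in range(10_000)])
        sd = np.degrees(circstd(np.radians(draws)))
        assert abs(sd - 45.0) / 45.0 < 0.02


class TestDistanceAndJumps:
    def test_increasing_distance_closed_form(self, default_config):
        d = distance_trajectory(default_config, INCREASING)
        i = int(round(10.0 * default_config.sample_rate_hz))
        assert np.isclose(d[i], 1.3)

    def test_decreasing_clamped_at_zero(self, default_config):
        d = distance_trajectory(default_config, DECREASING)
        # unclamped end would be 5 - 0.13*40 = -0.2
        assert d[-1] == 0.0
        assert np.all(np.diff(d) <= 0)

    def test_zero_speed_constant(self):
        cfg = ParadigmConfig(distance_speed_deg_s=0.0)
        assert np.all(distance_trajectory(cfg, DECREASING) == 5.0)

    def test_inconsistent_start_rejected(self, default_config):
        with pytest.raises(ConfigError):
            distance_trajectory(default_config, INCREASING, start_distance_deg=5.0)

    def test_jump_times_closed_form(self, default_config):
        jd = np.array(default_config.jump_distances_deg)
        np.testing.assert_allclose(jump_times_for_trend(default_config, INCREASING),
                                   jd / 0.13)
        np.testing.assert_allclose(jump_times_for_trend(default_config, DECREASING),
                                   (5.0 - jd[::-1]) / 0.13)

    def test_five_jumps_either_trend(self, default_config):
        assert len(jump_times_for_trend(default_config, INCREASING)) == 5
        assert len(jump_times_for_trend(default_config, DECREASING)) == 5


class TestContinuousTrial:
    def _spec(self, cond=FLANKED, trend=INCREASING, seed=3):
        return TrialSpec("continuous", cond, distance_trend=trend, seed=seed)

    def test_frame_count_and_jump_count(self, default_config):
        trace = generate_continuous_trial(self._spec(), default_config)
        assert trace.n_frames == 5760
        assert len(trace.jump_indices) == 5

    def test_rotation_speed_between_jumps(self, default_config):
        """|orientation change| integrates to 72 deg over any jump-free second."""
        trace = generate_continuous_trial(self._spec(), default_config)
        theta = trace.target_orientation_deg
        steps = np.abs(signed_diff_deg(theta[1:], theta[:-1]))
        jumpfree = np.ones(len(steps), dtype=bool)
        jumpfree[trace.jump_indices - 1] = False
        n = int(default_config.sample_rate_hz)
        start = trace.jump_indices[-1] + 1
        assert np.isclose(steps[start:start + n][jumpfree[start:start + n]].sum(),
                          72.0, atol=0.51)
        np.testing.assert_allclose(steps[jumpfree], 0.5)

    def test_gaps_keep_90_offsets_every_frame(self, default_config):
        trace = generate_continuous_trial(self._spec(), default_config)
        gaps = trace.flanker_gap_orientations_deg
        for k in range(1, 4):
            off = signed_diff_deg(gaps[:, k], gaps[:, 0]) % 360
            np.testing.assert_allclose(off, 90.0 * k)

    def test_orientation_channels_in_range(self, default_config):
        trace = generate_continuous_trial(self._spec(), default_config)
        assert np.all((trace.target_orientation_deg >= 0)
                      & (trace.target_orientation_deg < 360))
        assert np.all((trace.flanker_gap_orientations_deg >= 0)
                      & (trace.flanker_gap_orientations_deg < 360))

    def test_zero_rotation_no_jumps_constant(self):
        cfg = ParadigmConfig(rotation_speed_deg_s=0.0, jump_distances_deg=())
        trace = generate_continuous_trial(self._spec(), cfg)
        assert len(trace.jump_indices) == 0
        assert np.unique(trace.target_orientation_deg).size == 1

    def test_isolated_has_no_flanker_channels_but_distance_axis(self, default_config):
        trace = generate_continuous_trial(self._spec(cond=ISOLATED), default_config)
        assert trace.flanker_gap_orientations_deg is None
        assert trace.flanker_distance_deg.size == trace.n_frames

    def test_determinism(self, default_config):
        a = generate_continuous_trial(self._spec(), default_config)
        b = generate_continuous_trial(self._spec(), default_config)
        np.testing.assert_array_equal(a.target_orientation_deg,
                                      b.target_orientation_deg)


class TestSchedules:
    def test_block_composition(self, default_config):
        specs = build_block_schedule(default_config, np.random.default_rng(0))
        assert len(specs) == 12
        flanked = [s for s in specs if s.condition == FLANKED]
        isolated = [s for s in specs if s.condition == ISOLATED]
        assert len(flanked) == 8 and len(isolated) == 4
        assert sum(s.distance_trend == INCREASING for s in flanked) == 4
        assert sum(s.distance_trend == INCREASING for s in isolated) == 2

    def test_isolated_shares_flanked_jump_times(self, default_config):
        specs = build_block_schedule(default_config, np.random.default_rng(0))
        for trend in (INCREASING, DECREASING):
            times = {s.jump_times_s for s in specs if s.distance_trend == trend}
            assert len(times) == 1  # identical across conditions

    def test_block_order_deterministic(self, default_config):
        a = build_block_schedule(default_config, np.random.default_rng(9))
        b = build_block_schedule(default_config, np.random.default_rng(9))
        assert [s.trial_id for s in a] == [s.trial_id for s in b]

    def test_trial_based_composition(self, default_config):
        specs = build_trial_based_schedule(default_config, np.random.default_rng(0))
        assert len(specs) == 200
        for d in default_config.trial_based_distances_deg:
            assert sum(s.condition == FLANKED and s.fixed_distance_deg == d
                       for s in specs) == 25
        assert sum(s.condition == ISOLATED for s in specs) == 25

    def test_trial_based_single_rep(self):
        cfg = ParadigmConfig(trial_based_reps=1)
        assert len(build_trial_based_schedule(cfg, np.random.default_rng(0))) == 8
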