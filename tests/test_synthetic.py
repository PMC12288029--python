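"""Generator tests: crossover design, series tier, and video tier."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from preyflow import synthetic
from preyflow.synthetic import ArenaConfig, SeriesConfig, TrialMetadata


class TestCrossoverDesign:
    def test_default_design_has_91_trials_with_stated_exclusions(self, default_trials):
        assert len(default_trials) == 91
        counts = Counter(t.treatment for t in default_trials)
        assert counts == {"control": 24, "warm": 22, "turbid": 22, "interaction": 23}

    def test_no_exclusion_design_is_balanced(self):
        trials = synthetic.design_crossover(n_groups=8, exclusions=(), master_seed=3)
        assert len(trials) == 32
        # every (group, treatment) pair exactly once
        pairs = Counter((t.trial_id[:3], t.treatment) for t in trials)
        assert set(pairs.values()) == {1}
        # each treatment occupies each order position equally often
        by_order = Counter((t.treatment, t.trial_order) for t in trials)
        assert set(by_order.values()) == {2}

    def test_single_group_orders_form_permutation(self):
        trials = synthetic.design_crossover(n_groups=1, exclusions=(), master_seed=0)
        assert len(trials) == 4
        assert sorted(t.trial_order for t in trials) == [1, 2, 3, 4]
        assert {t.treatment for t in trials} == set(synthetic.TREATMENTS)

    def test_same_master_seed_reproduces_experiment(self):
        t1, s1 = synthetic.simulate_experiment(n_groups=2, exclusions=(), master_seed=7, n_frames=200)
        t2, s2 = synthetic.simulate_experiment(n_groups=2, exclusions=(), master_seed=7, n_frames=200)
        assert t1 == t2
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a, b)

    def test_tanks_assigned_evenly(self, default_trials):
        tanks = Counter(t.tank for t in default_trials)
        assert set(tanks) == {1, 2, 3, 4}
        # 6 groups per tank x 4 trials, minus at most the 5 exclusions
        assert all(19 <= c <= 24 for c in tanks.values())

    def test_nonpositive_group_count_rejected(self):
        with pytest.raises(ValueError):
            synthetic.design_crossover(n_groups=0)

    def test_metadata_invariants_enforced(self):
        with pytest.raises(ValueError):
            TrialMetadata("x", 25, 0, 1, 30, 1, 600, 100, 0)  # bad treatment cell
        with pytest.raises(ValueError):
            TrialMetadata("x", 22, 0, 1, 30, 5, 600, 100, 0)  # bad order
        with pytest.raises(ValueError):
            TrialMetadata("x", 22, 0, 1, 40, 1, 600, 100, 0)  # group size out of range


class TestSeriesTier:
    def test_null_effect_factors_make_treatments_identical(self):
        cfg = SeriesConfig(temp_amplitude_factor=1.0, turb_rate_factor=1.0, turb_duration_factor=1.0, seed=5)
        series = {
            name: synthetic.simulate_magnitude_series(cfg, name, 2000)
            for name in synthetic.TREATMENTS
        }
        base = series["control"]
        for other in series.values():
            np.testing.assert_array_equal(base, other)

    def test_no_visits_matches_noise_floor_quantile(self):
        cfg = SeriesConfig(visit_rate=0.0, seed=9)
        values = np.concatenate(
            [synthetic.simulate_magnitude_series(cfg, "control", 50_000, seed=s)[1:] for s in range(4)]
        )
        q99 = np.percentile(values, 99)
        expected = stats.gamma.ppf(0.99, cfg.noise_floor_shape, scale=cfg.noise_floor_scale)
        assert q99 == pytest.approx(expected, rel=0.03)

    def test_visit_count_matches_poisson_mean(self):
        # 2 visits/min over 11 min -> Poisson(22)
        cfg = SeriesConfig(visit_rate=2.0)
        n_frames = 19_800
        reps = 200
        counts = [
            synthetic.simulate_magnitude_series(cfg, "control", n_frames, seed=s, return_visits=True)[1]
            for s in range(reps)
        ]
        mean = np.mean(counts)
        tol = 3 * np.sqrt(22 / reps)  # 3 SDs of the Monte-Carlo mean
        assert abs(mean - 22) < tol

    def test_series_nonnegative_and_first_value_zero(self):
        values = synthetic.simulate_magnitude_series(SeriesConfig(seed=2), "interaction", 5000)
        assert values[0] == 0.0
        assert np.all(values >= 0)
        assert len(values) == 5000

    def test_turbidity_reduces_event_frequency(self):
        # sign test over replicate pairs: turbid trials cross a fixed
        # threshold less often when the visit rate is halved
        cfg = SeriesConfig(seed=0)
        wins = 0
        reps = 12
        for s in range(reps):
            clear = synthetic.simulate_magnitude_series(cfg, "control", 19_800, seed=1000 + s)
            turbid = synthetic.simulate_magnitude_series(cfg, "turbid", 19_800, seed=2000 + s)
            thr = np.percentile(np.concatenate([clear, turbid]), 95)
            from preyflow.detection import group_events

            wins += len(group_events(clear > thr)) > len(group_events(turbid > thr))
        assert wins > reps / 2

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SeriesConfig(noise_floor_scale=0.0)
        with pytest.raises(ValueError):
            SeriesConfig(turb_rate_factor=-1.0)
        with pytest.raises(ValueError):
            synthetic.simulate_magnitude_series(SeriesConfig(), "control", 1)
        with pytest.raises(ValueError):
            synthetic.simulate_magnitude_series(SeriesConfig(), "murky", 100)


class TestVideoTier:
    def test_no_fish_no_noise_gives_static_frames(self):
        cfg = ArenaConfig(n_fish=0, noise_sd=0.0, n_frames=5, seed=0)
        frames = synthetic.simulate_trial_video(cfg, "control")
        for t in range(1, 5):
            np.testing.assert_array_equal(frames[t], frames[0])

    def test_turbidity_attenuates_distant_fish_contrast(self):
        cfg = ArenaConfig(n_fish=3, noise_sd=0.0, n_frames=4, turbidity_beta=0.05, seed=11)
        clear = synthetic.simulate_trial_video(cfg, "control")
        turbid = synthetic.simulate_trial_video(cfg, "turbid")
        c_clear = np.abs(clear - cfg.background_level)
        c_turbid = np.abs(turbid - cfg.background_level)
        assert np.all(c_turbid <= c_clear + 1e-12)
        assert c_turbid.max() < c_clear.max()

    def test_speed_multiplier_scales_path_length_exactly(self):
        slow = ArenaConfig(frame_size=(128, 128), n_fish=3, n_frames=50, base_speed=1.0,
                           temp_speed_multiplier=1.0, seed=4)
        fast = ArenaConfig(frame_size=(128, 128), n_fish=3, n_frames=50, base_speed=1.0,
                           temp_speed_multiplier=2.0, seed=4)
        p_slow = synthetic.simulate_fish_tracks(slow, "warm")
        p_fast = synthetic.simulate_fish_tracks(fast, "warm")
        len_slow = np.linalg.norm(np.diff(p_slow, axis=0), axis=2).sum(axis=0)
        len_fast = np.linalg.norm(np.diff(p_fast, axis=0), axis=2).sum(axis=0)
        np.testing.assert_allclose(len_fast, 2.0 * len_slow, rtol=1e-9)

    def test_fish_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            ArenaConfig(frame_size=(16, 16), fish_axis_px=(10.0, 9.0))

    def test_frames_clipped_to_unit_interval(self):
        cfg = ArenaConfig(n_fish=4, noise_sd=0.1, n_frames=3, seed=2)
        frames = synthetic.simulate_trial_video(cfg, "interaction")
        assert frames.min() >= 0.0 and frames.max() <= 1.0
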