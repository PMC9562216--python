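import numpy as np
import pytest
from scipy.stats import chisquare

from gaitevents import (GaitEvent, SimConfig, assemble_features, canonicalize,
                        classify_ic_pattern, compute_velocities,
                        downsample_trial, encode_gaussian_targets,
                        extract_training_window, prepare_trial,
                        simulate_trial)
from gaitevents.preprocessing import MarkerCombo, Scaler
from gaitevents.simulate import MARKER_GEOMETRY


class TestDownsample:
    def test_decimation_halves_300hz_trial(self):
        trial = simulate_trial(SimConfig(pattern="HS", n_strides=3,
                                         rate_hz=300.0, seed=1))
        down = downsample_trial(trial, 150.0)
        assert down.rate == 150.0
        assert down.n_frames == -(-trial.n_frames // 2)
        # decimation keeps every second frame exactly
        np.testing.assert_array_equal(
            down.marker("HEE", "R").positions,
            trial.marker("HEE", "R").positions[::2])

    def test_identity_at_target_rate(self, hs_trial):
        assert downsample_trial(hs_trial, 150.0) is hs_trial

    def test_linear_ramp_lands_on_ramp(self):
        trial = simulate_trial(SimConfig(pattern="MF", n_strides=2,
                                         rate_hz=300.0, seed=2))
        # overwrite one marker with an exact linear ramp
        m = trial.marker("TOE", "R")
        n = m.n_frames
        m.positions[:] = np.linspace(0, 100, n)[:, None] * [1.0, 2.0, 3.0]
        down = downsample_trial(trial, 150.0)
        expect = m.positions[::2]
        np.testing.assert_allclose(
            down.marker("TOE", "R").positions, expect, atol=1e-12)

    def test_upsampling_rejected(self, hs_trial):
        with pytest.raises(ValueError):
            downsample_trial(hs_trial, 300.0)

    def test_event_times_unchanged(self):
        trial = simulate_trial(SimConfig(pattern="HS", n_strides=3,
                                         rate_hz=300.0, seed=3))
        down = downsample_trial(trial, 150.0)
        assert [e.time_s for e in down.events] == \
            [e.time_s for e in trial.events]


class TestVelocities:
    def test_constant_position_zero_velocity(self):
        pos = np.ones((10, 3)) * 7.0
        np.testing.assert_array_equal(compute_velocities(pos, 150.0), 0.0)

    def test_unit_ramp_at_150hz_gives_150(self):
        pos = np.array([[0.0], [1.0], [2.0]])
        v = compute_velocities(pos, 150.0)
        np.testing.assert_allclose(v, 150.0)
        assert v.shape == pos.shape  # last frame padded

    def test_sine_matches_difference_quotient_not_derivative(self):
        rate = 150.0
        t = np.arange(100) / rate
        pos = np.sin(2 * np.pi * 5 * t)[:, None]
        v = compute_velocities(pos, rate)
        expect = (pos[1:] - pos[:-1]) * rate  # the forward quotient itself
        np.testing.assert_allclose(v[:-1], expect, atol=1e-12)
        analytic = 2 * np.pi * 5 * np.cos(2 * np.pi * 5 * t)[:-1, None]
        assert np.max(np.abs(v[:-1] - analytic)) > 0.1  # visibly not d/dt

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            compute_velocities(np.zeros((1, 3)), 150.0)


class TestCanonicalize:
    def test_progression_rotated_to_plus_x(self):
        trial = simulate_trial(SimConfig(pattern="HS", n_strides=4, seed=5))
        # walk in -x: mirror the x axis
        for m in trial.markers:
            m.positions[:, 0] *= -1
        canon = canonicalize(trial)
        hee = canon.marker("HEE", "R").positions
        assert hee[-1, 0] - hee[0, 0] > 0

    def test_left_trial_mirrors_onto_right(self):
        cfg = dict(pattern="FF", n_strides=4, seed=6, noise_sd_mm=0.0)
        right = canonicalize(simulate_trial(SimConfig(side="R", **cfg)))
        left = canonicalize(simulate_trial(SimConfig(side="L", **cfg)))
        for mid in ("HEE", "TOE", "HLX", "PMT5"):
            np.testing.assert_allclose(
                left.marker(mid, "L").positions,
                right.marker(mid, "R").positions, atol=1e-9)

    def test_idempotent(self, hs_trial):
        once = canonicalize(hs_trial)
        twice = canonicalize(once)
        for m1, m2 in zip(once.markers, twice.markers):
            np.testing.assert_allclose(m2.positions, m1.positions, atol=1e-9)

    def test_standing_trial_rejected(self, hs_trial):
        trial = simulate_trial(SimConfig(pattern="HS", n_strides=2, seed=9))
        for m in trial.markers:
            m.positions[:] = m.positions[0]
        with pytest.raises(ValueError, match="progression"):
            canonicalize(trial)


class TestAssembleFeatures:
    @pytest.mark.parametrize("combo, channels", [
        ("TOE|HEE", 12),
        ("HLX|HEE", 12),
        ("HLX|PMT5|HEE", 18),
        ("TOE|PMT5|HEE", 18),
        ("HLX|TOE|HEE", 18),
        ("HEE", 6),
    ])
    def test_channel_count_is_six_per_marker(self, hs_trial, combo, channels):
        feats = assemble_features(canonicalize(hs_trial), combo)
        assert feats.n_channels == channels
        assert feats.n_channels == 6 * len(MarkerCombo.from_name(combo).markers)

    def test_channel_layout_positions_then_velocities(self, hs_trial):
        feats = assemble_features(canonicalize(hs_trial), "TOE|HEE")
        kinds = [k for _, _, k in feats.layout]
        assert kinds == ["position"] * 3 + ["velocity"] * 3 + \
            ["position"] * 3 + ["velocity"] * 3

    def test_absent_marker_errors(self, hs_trial):
        trial = canonicalize(hs_trial)
        trial.markers = [m for m in trial.markers if m.marker_id != "HLX"]
        with pytest.raises(KeyError):
            assemble_features(trial, "HLX|HEE")

    def test_scaler_standardizes_channels(self, hs_trial):
        feats = assemble_features(canonicalize(hs_trial), "TOE|HEE")
        scaler = Scaler.fit([feats.values])
        scaled = assemble_features(canonicalize(hs_trial), "TOE|HEE",
                                   scaler=scaler)
        np.testing.assert_allclose(scaled.values.mean(axis=0), 0, atol=1e-9)
        stds = scaled.values.std(axis=0)
        varying = feats.values.std(axis=0) > 1e-9
        np.testing.assert_allclose(stds[varying], 1, atol=1e-9)
        # constant channels (the lateral axis in a straight-line walk)
        np.testing.assert_allclose(stds[~varying], 0, atol=1e-9)

    def test_duplicate_marker_combo_rejected(self):
        with pytest.raises(ValueError):
            MarkerCombo(("HEE", "HEE"))


class TestTrainingWindows:
    def _features_and_event(self, n_frames=1000, event_frame=500):
        rate = 150.0
        values = np.arange(n_frames, dtype=float)[:, None] * np.ones(6)
        from gaitevents.preprocessing import FeatureMatrix
        feats = FeatureMatrix(values, rate,
                              MarkerCombo(("HEE",)).channel_layout())
        event = GaitEvent("IC", event_frame / rate, "R", "synthetic")
        targets = encode_gaussian_targets([event.time_s],
                                          feats.frame_times).values
        return feats, event, targets

    def test_zero_offset_window_is_centered(self):
        feats, event, targets = self._features_and_event()
        win = extract_training_window(feats, event, targets,
                                      max_offset=0)
        assert win.features.n_frames == 150
        # frames 425..574 inclusive
        assert win.features.values[0, 0] == 425
        assert win.features.values[-1, 0] == 574
        assert win.offset_frames == 0

    def test_same_seed_same_offset(self):
        feats, event, targets = self._features_and_event()
        draws = [extract_training_window(
            feats, event, targets, rng=np.random.default_rng(7)).offset_frames
            for _ in range(2)]
        assert draws[0] == draws[1]

    def test_offset_uniform_over_61_values(self):
        feats, event, targets = self._features_and_event()
        rng = np.random.default_rng(0)
        deltas = [extract_training_window(feats, event, targets,
                                          rng=rng).offset_frames
                  for _ in range(10_000)]
        counts = np.bincount(np.array(deltas) + 30, minlength=61)
        assert counts.size == 61
        stat, p = chisquare(counts)
        assert p > 0.01

    def test_edge_window_clamped_not_padded(self):
        feats, event, targets = self._features_and_event(event_frame=10)
        win = extract_training_window(feats, event, targets,
                                      rng=np.random.default_rng(1))
        assert win.features.n_frames == 150
        assert win.features.values[0, 0] == 0  # shifted inward to the start

    def test_short_trial_rejected(self):
        feats, event, targets = self._features_and_event(n_frames=100,
                                                         event_frame=50)
        with pytest.raises(ValueError):
            extract_training_window(feats, event, targets)

    def test_window_always_contains_its_event(self):
        feats, event, targets = self._features_and_event()
        rng = np.random.default_rng(3)
        for _ in range(200):
            win = extract_training_window(feats, event, targets, rng=rng)
            t0 = win.features.frame_times[0]
            t1 = win.features.frame_times[-1]
            assert t0 <= event.time_s <= t1


class TestPatternClassification:
    def test_simulated_patterns_recovered(self, hs_trial, mf_trial, ff_trial):
        for trial, expect in ((hs_trial, "HS"), (mf_trial, "MF"),
                              (ff_trial, "FF")):
            ics = trial.events_of("IC")
            assert classify_ic_pattern(trial, ics) == expect

    def test_flat_contact_within_margin_is_mf(self, mf_trial):
        # marker mount-height differences are below the 5 mm margin
        ics = mf_trial.events_of("IC")
        assert classify_ic_pattern(mf_trial, ics,
                                   contact_margin_mm=5.0) == "MF"

    def test_no_ic_events_rejected(self, hs_trial):
        with pytest.raises(ValueError):
            classify_ic_pattern(hs_trial, [])

    def test_angle_mode_recovers_patterns(self, hs_trial, ff_trial):
        from gaitevents.preprocessing import classify_ic_pattern_by_angle
        assert classify_ic_pattern_by_angle(
            hs_trial, hs_trial.events_of("IC")) == "HS"
        assert classify_ic_pattern_by_angle(
            ff_trial, ff_trial.events_of("IC")) == "FF"
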