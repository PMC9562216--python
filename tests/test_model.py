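import numpy as np
import pytest

from gaitevents import (HYPERPARAM_PRESETS, SimConfig, TrainConfig,
                        balanced_group_sampler, predict_scores,
                        simulate_trial, split_by_subject, train_detector)
from gaitevents.model import (DetectorHyperParams, TrainedDetector,
                              aggregate_runs, auto_pos_weight, fast_profile)
from gaitevents.pipeline import build_windows, prepare_trial
from gaitevents.preprocessing import MarkerCombo


class TestPresets:
    def test_all_ten_event_combo_presets_exist(self):
        assert len(HYPERPARAM_PRESETS) == 10
        for ev in ("IC", "TO"):
            for combo in ("HLX|HEE", "TOE|HEE", "HLX|PMT5|HEE",
                          "TOE|PMT5|HEE", "HLX|TOE|HEE"):
                hp = HYPERPARAM_PRESETS[f"{ev}:{combo}"]
                assert hp.n_input_features == \
                    MarkerCombo.from_name(combo).n_channels
                assert hp.dropout == 0.3
                assert hp.learning_rate == 0.001

    def test_tuned_rows_spot_checked(self):
        hp = HYPERPARAM_PRESETS["IC:TOE|HEE"]
        assert (hp.n_input_features, hp.n_recurrent_layers,
                hp.hidden_size) == (12, 5, 256)
        hp = HYPERPARAM_PRESETS["TO:TOE|HEE"]
        assert (hp.n_recurrent_layers, hp.hidden_size) == (2, 512)
        hp = HYPERPARAM_PRESETS["IC:HLX|HEE"]
        assert (hp.n_recurrent_layers, hp.hidden_size) == (2, 512)

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            DetectorHyperParams(12, 0, 256, 0.3, 0.001)
        with pytest.raises(ValueError):
            DetectorHyperParams(12, 2, 256, 1.0, 0.001)


class TestSplit:
    def test_ten_subjects_split_8_1_1(self):
        ids = [f"s{i}" for i in range(10)]
        train, val, test = split_by_subject(ids, seed=0)
        assert (len(train), len(val), len(test)) == (8, 1, 1)

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(23)]
        a = split_by_subject(ids, seed=5)
        b = split_by_subject(list(reversed(ids)), seed=5)
        assert a == b

    def test_partition_is_disjoint_and_exhaustive(self):
        ids = [f"s{i}" for i in range(37)]
        train, val, test = split_by_subject(ids, seed=3)
        assert train | val | test == set(ids)
        assert not (train & val or train & test or val & test)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            split_by_subject(["a", "b"])
        with pytest.raises(ValueError):
            split_by_subject([])


class _FakeWindow:
    """Minimal stand-in carrying only the group label."""

    def __init__(self, group):
        self.group = group


class TestBalancedSampler:
    def test_4_2_1_ratio_within_3_sd(self):
        samples = ([_FakeWindow("HS")] * 5 + [_FakeWindow("MF")] * 5
                   + [_FakeWindow("FF")] * 5)
        rng = np.random.default_rng(0)
        stream = balanced_group_sampler(samples,
                                        {"HS": 4, "MF": 2, "FF": 1}, rng)
        n = 7000
        counts = {"HS": 0, "MF": 0, "FF": 0}
        for _ in range(n):
            counts[next(stream).group] += 1
        for g, p in (("HS", 4 / 7), ("MF", 2 / 7), ("FF", 1 / 7)):
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts[g] - n * p) < 3 * sd

    def test_degenerate_ratio_draws_single_group(self):
        samples = [_FakeWindow("HS"), _FakeWindow("MF")]
        stream = balanced_group_sampler(samples, {"HS": 1, "MF": 0, "FF": 0},
                                        np.random.default_rng(1))
        assert all(next(stream).group == "HS" for _ in range(50))

    def test_empty_positive_ratio_group_rejected(self):
        samples = [_FakeWindow("HS"), _FakeWindow("FF")]
        with pytest.raises(ValueError, match="MF"):
            next(balanced_group_sampler(samples, {"HS": 4, "MF": 2, "FF": 1},
                                        np.random.default_rng(2)))


def _tiny_windows(n_subjects=6, event_type="IC", combo="TOE|HEE", seed=0):
    from gaitevents import simulate_cohort
    trials = simulate_cohort(n_subjects, {"HS": 1, "MF": 1, "FF": 1},
                             seed=seed, n_strides=3, noise_sd_mm=0.5)
    cfg = TrainConfig(seed=seed, max_epochs=0)
    rng = np.random.default_rng(seed)
    return build_windows(trials, event_type, combo, cfg, rng)


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self):
        windows = _tiny_windows()
        cfg = TrainConfig(seed=0, max_epochs=0)
        det = train_detector(windows, [], fast_profile(12), cfg)
        assert det.history == []
        feats, _ = prepare_trial(
            simulate_trial(SimConfig(pattern="HS", n_strides=3, seed=5)),
            "TOE|HEE")
        scores = predict_scores(det, feats)
        assert scores.shape == (feats.n_frames,)
        assert np.all((scores > 0) & (scores < 1))

    def test_all_zero_targets_drive_scores_down(self):
        windows = _tiny_windows()
        for w in windows:
            w.targets = np.zeros_like(w.targets)
        cfg = TrainConfig(seed=0, max_epochs=25, batch_size=16,
                          pos_weight=1.0, patience=25)
        det = train_detector(windows[:-4], windows[-4:], fast_profile(12),
                             cfg)
        held = np.concatenate([predict_scores(det, w.features)
                               for w in windows[-4:]])
        assert held.mean() < 0.1

    def test_training_reproducible_given_seed(self):
        windows = _tiny_windows()
        cfg = TrainConfig(seed=7, max_epochs=2, batch_size=16)
        h1 = train_detector(windows[:-4], windows[-4:], fast_profile(12),
                            cfg).history
        h2 = train_detector(windows[:-4], windows[-4:], fast_profile(12),
                            cfg).history
        assert h1 == h2

    def test_channel_mismatch_rejected(self):
        windows = _tiny_windows(combo="TOE|HEE")
        cfg = TrainConfig(seed=0, max_epochs=1)
        with pytest.raises(ValueError, match="channels"):
            train_detector(windows, [], fast_profile(18), cfg,
                           combo="HLX|PMT5|HEE")

    def test_checkpoint_round_trip(self, tmp_path):
        windows = _tiny_windows()
        cfg = TrainConfig(seed=1, max_epochs=1, batch_size=16)
        det = train_detector(windows[:-4], windows[-4:], fast_profile(12),
                             cfg)
        path = tmp_path / "ckpt.npz"
        det.save(path)
        back = TrainedDetector.load(path)
        assert back.event_type == det.event_type
        assert back.combo.name == det.combo.name
        assert back.hyper == det.hyper
        assert back.history == det.history
        feats = windows[0].features
        np.testing.assert_array_equal(predict_scores(back, feats),
                                      predict_scores(det, feats))


class TestAutoPosWeight:
    def test_matches_negative_to_positive_mass_ratio(self):
        t = [np.array([1.0, 0.0, 0.0, 0.0])]
        assert auto_pos_weight(t) == pytest.approx(3.0)

    def test_all_zero_targets_fall_back_to_one(self):
        assert auto_pos_weight([np.zeros(10)]) == 1.0


class TestRepeatedTraining:
    def test_runs_use_distinct_validation_splits_and_aggregate(self):
        from gaitevents import repeated_training_protocol
        windows = _tiny_windows()
        pool = {}
        for w in windows:
            pool.setdefault(w.subject_id, []).append(w)
        seen_val_losses = []

        def evaluate_run(det):
            seen_val_losses.append(det.history[-1]["val_loss"])
            return {"recall_pct": 100.0 - len(seen_val_losses)}

        cfg = TrainConfig(seed=3, max_epochs=1, batch_size=16)
        per_run, agg, dets = repeated_training_protocol(
            pool, evaluate_run, fast_profile(12), cfg, n_runs=3)
        assert len(per_run) == len(dets) == 3
        assert agg["recall_pct"]["n_runs"] == 3
        assert agg["recall_pct"]["mean"] == pytest.approx(98.0)
        # runs differ: different seeds and train/val splits
        assert len({d.seed for d in dets}) == 3

    def test_zero_runs_rejected(self):
        from gaitevents import repeated_training_protocol
        with pytest.raises(ValueError):
            repeated_training_protocol({}, lambda d: {}, fast_profile(12),
                                       TrainConfig(), n_runs=0)


class TestAggregateRuns:
    def test_sem_is_sd_over_sqrt_n(self):
        runs = [{"recall": v} for v in (80.0, 84.0, 88.0)]
        agg = aggregate_runs(runs)
        assert agg["recall"]["mean"] == pytest.approx(84.0)
        expect = np.std([80, 84, 88], ddof=1) / np.sqrt(3)
        assert agg["recall"]["sem"] == pytest.approx(expect)

    def test_single_run_sem_flagged_nan(self):
        agg = aggregate_runs([{"recall": 90.0}])
        assert np.isnan(agg["recall"]["sem"])
        assert agg["recall"]["n_runs"] == 1

    def test_identical_metric_gives_zero_sem(self):
        agg = aggregate_runs([{"m": 5.0}, {"m": 5.0}, {"m": 5.0}])
        assert agg["m"]["sem"] == 0.0
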