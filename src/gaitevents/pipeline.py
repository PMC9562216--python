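"""End-to-end glue: trial -> features -> windows -> detector -> report.

These helpers chain the preprocessing, encoding, model and evaluation
stages in the standard order (downsample to 150 Hz, canonicalize,
assemble features, encode Gaussian targets, cut windows / run inference,
peak-detect, match within tolerance).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .detection import (DetectionConfig, EvaluationReport, detect_events,
                        evaluate_detection, match_events)
from .io import Trial
from .model import TrainConfig, TrainedDetector, predict_scores
from .preprocessing import (FeatureMatrix, MarkerCombo, WindowSample,
                            assemble_features, canonicalize,
                            classify_ic_pattern, downsample_trial,
                            extract_training_window)
from .targets import EncoderConfig, encode_gaussian_targets


def prepare_trial(trial: Trial, combo: MarkerCombo | str,
                  target_rate: float = 150.0) -> tuple[FeatureMatrix, str]:
    """Downsample, canonicalize and assemble features for one foot."""
    if isinstance(combo, str):
        combo = MarkerCombo.from_name(combo)
    if trial.rate > target_rate:
        trial = downsample_trial(trial, target_rate)
    trial = canonicalize(trial)
    sides = {m.side for m in trial.markers}
    side = sorted(sides)[0] if len(sides) == 1 else "R"
    return assemble_features(trial, combo, side=side), side


def trial_group(trial: Trial) -> str:
    """The trial's gait group: stored label, else marker-height rule."""
    if trial.pattern:
        return trial.pattern
    ics = trial.events_of("IC")
    return classify_ic_pattern(trial, ics)


def build_windows(trials: Sequence[Trial], event_type: str,
                  combo: MarkerCombo | str, config: TrainConfig,
                  rng: np.random.Generator,
                  encoder: EncoderConfig = EncoderConfig(),
                  windows_per_event: int = 1) -> list[WindowSample]:
    """Cut training windows around every annotated event of a type."""
    if isinstance(combo, str):
        combo = MarkerCombo.from_name(combo)
    out: list[WindowSample] = []
    for trial in trials:
        features, side = prepare_trial(trial, combo)
        events = [e for e in trial.events_of(event_type)
                  if e.side == side or len({m.side
                                            for m in trial.markers}) == 1]
        if not events:
            continue
        targets = encode_gaussian_targets(
            [e.time_s for e in events], features.frame_times, encoder,
            event_type).values
        group = trial_group(trial)
        for ev in events:
            for _ in range(windows_per_event):
                out.append(extract_training_window(
                    features, ev, targets,
                    length_frames=config.window_length,
                    max_offset=config.max_offset, rng=rng,
                    group=group, subject_id=trial.subject_id))
    return out


def evaluate_on_trials(detector: TrainedDetector, trials: Sequence[Trial],
                       config: DetectionConfig = DetectionConfig()
                       ) -> EvaluationReport:
    """Full-sequence inference + peak detection + tolerance matching."""
    matches, labels = [], []
    for trial in trials:
        features, side = prepare_trial(trial, detector.combo)
        scores = predict_scores(detector, features)
        predicted = detect_events(scores, features.frame_times, config,
                                  event_type=detector.event_type, side=side)
        truth = trial.events_of(detector.event_type)
        matches.append(match_events(predicted, truth, config.tolerance_ms))
        labels.append(trial_group(trial))
    return evaluate_detection(matches, labels)
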