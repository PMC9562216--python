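"""Detector training: subject-level splits, balanced group sampling,
weighted cross-entropy, the Adam training loop and the repeated-training
protocol.

One detector is trained per (event type, marker combination).  The
named hyper-parameter presets reproduce the reference protocol's tuned
settings for each of the ten event/combination pairs; a lightweight
``test`` profile (1 layer, 64 hidden units) exists for fast runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

from ._network import Adam, BiLSTM, clip_grad_norm, weighted_bce_from_logits
from .preprocessing import FeatureMatrix, MarkerCombo, Scaler, WindowSample


@dataclass(frozen=True)
class DetectorHyperParams:
    n_input_features: int
    n_recurrent_layers: int
    hidden_size: int
    dropout: float
    learning_rate: float

    def __post_init__(self) -> None:
        if min(self.n_input_features, self.n_recurrent_layers,
               self.hidden_size) <= 0 or self.learning_rate <= 0:
            raise ValueError("hyper-parameters must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


#: Tuned hyper-parameters per event type and marker combination.
HYPERPARAM_PRESETS: dict[str, DetectorHyperParams] = {
    "IC:HLX|HEE": DetectorHyperParams(12, 2, 512, 0.3, 0.001),
    "IC:TOE|HEE": DetectorHyperParams(12, 5, 256, 0.3, 0.001),
    "IC:HLX|PMT5|HEE": DetectorHyperParams(18, 2, 256, 0.3, 0.001),
    "IC:TOE|PMT5|HEE": DetectorHyperParams(18, 5, 256, 0.3, 0.001),
    "IC:HLX|TOE|HEE": DetectorHyperParams(18, 2, 512, 0.3, 0.001),
    "TO:HLX|HEE": DetectorHyperParams(12, 5, 256, 0.3, 0.001),
    "TO:TOE|HEE": DetectorHyperParams(12, 2, 512, 0.3, 0.001),
    "TO:HLX|PMT5|HEE": DetectorHyperParams(18, 2, 256, 0.3, 0.001),
    "TO:TOE|PMT5|HEE": DetectorHyperParams(18, 5, 256, 0.3, 0.001),
    "TO:HLX|TOE|HEE": DetectorHyperParams(18, 2, 256, 0.3, 0.001),
}


def fast_profile(n_input_features: int) -> DetectorHyperParams:
    """Small profile (1 layer, 64 hidden) for fast desk-scale runs."""
    return DetectorHyperParams(n_input_features, 1, 64, 0.0, 0.003)


@dataclass
class TrainConfig:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    group_ratio: Mapping[str, float] = field(
        default_factory=lambda: {"HS": 4.0, "MF": 2.0, "FF": 1.0})
    window_length: int = 150
    max_offset: int = 30
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    pos_weight: float | None = None  # None -> computed from training targets
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(r < 0 for r in self.group_ratio.values()):
            raise ValueError("group ratio entries must be >= 0")


# ---------------------------------------------------------------------------
# Dataset splitting and sampling
# ---------------------------------------------------------------------------

def split_by_subject(subject_ids: Sequence[str],
                     fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0) -> tuple[set[str], set[str], set[str]]:
    """Partition subjects into disjoint train/validation/test sets.

    Every subject lands in exactly one subset (no window of one subject
    can leak across splits).  Sizes follow the rounded fractions with
    the remainder assigned to the training set; the shuffle is
    deterministic given ``seed`` and independent of input order.
    """
    ids = sorted(set(subject_ids))
    if not ids:
        raise ValueError("empty subject list")
    if len(ids) < 3:
        raise ValueError("need at least 3 subjects to split")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(order)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_val, n_test = max(n_val, 1), max(n_test, 1)
    test = set(order[:n_test])
    val = set(order[n_test:n_test + n_val])
    train = set(order[n_test + n_val:])
    if not train:
        raise ValueError("split left the training set empty")
    return train, val, test


def balanced_group_sampler(samples: Sequence[WindowSample],
                           ratio: Mapping[str, float],
                           rng: np.random.Generator
                           ) -> Iterator[WindowSample]:
    """Endless stream sampling gait groups at the given ratio.

    Each draw first picks group g with probability ratio_g / sum(ratio),
    then a sample uniformly within that group (with replacement).  A
    group with positive ratio but no samples is an error.
    """
    groups = [g for g, r in ratio.items() if r > 0]
    if not groups:
        raise ValueError("all group ratios are zero")
    by_group: dict[str, list[WindowSample]] = {g: [] for g in groups}
    for s in samples:
        if s.group in by_group:
            by_group[s.group].append(s)
    for g in groups:
        if not by_group[g]:
            raise ValueError(f"group {g} has positive ratio but no samples")
    probs = np.array([ratio[g] for g in groups], dtype=float)
    probs /= probs.sum()
    while True:
        g = groups[rng.choice(len(groups), p=probs)]
        pool = by_group[g]
        yield pool[int(rng.integers(len(pool)))]


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def weighted_bce_loss(scores: np.ndarray, targets: np.ndarray,
                      pos_weight: float = 1.0) -> float:
    """Binary-weighted cross-entropy on probability scores.

    mean over frames of -[w y log p + (1-y) log(1-p)]; with w = 1 this
    is the standard binary cross-entropy.
    """
    p = np.asarray(scores, dtype=float)
    y = np.asarray(targets, dtype=float)
    if p.shape != y.shape:
        raise ValueError("scores and targets shapes differ")
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.mean(-(pos_weight * y * np.log(p)
                           + (1.0 - y) * np.log(1.0 - p))))


def auto_pos_weight(targets: Sequence[np.ndarray]) -> float:
    """Dataset-level positive-class weight sum(1-y)/sum(y)."""
    pos = sum(float(np.sum(t)) for t in targets)
    neg = sum(float(np.sum(1.0 - t)) for t in targets)
    if pos <= 0:
        return 1.0
    return neg / pos


# ---------------------------------------------------------------------------
# Trained detector container
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


@dataclass
class TrainedDetector:
    event_type: str
    combo: MarkerCombo
    hyper: DetectorHyperParams
    network: BiLSTM
    scaler: Scaler
    history: list[dict[str, float]]
    seed: int

    def __post_init__(self) -> None:
        if self.hyper.n_input_features != self.combo.n_channels:
            raise ValueError(
                f"hyper-params expect {self.hyper.n_input_features} inputs "
                f"but combo {self.combo.name} yields {self.combo.n_channels}")

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameters + metadata + scaler stats."""
        meta = {
            "format_version": CHECKPOINT_VERSION,
            "event_type": self.event_type,
            "combo": self.combo.name,
            "hyper": self.hyper.__dict__,
            "history": self.history,
            "seed": self.seed,
        }
        np.savez(path, __meta__=json.dumps(meta),
                 __scaler_mean__=self.scaler.mean,
                 __scaler_std__=self.scaler.std,
                 **self.network.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedDetector":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            if meta["format_version"] != CHECKPOINT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version "
                    f"{meta['format_version']}")
            hyper = DetectorHyperParams(**meta["hyper"])
            net = BiLSTM(hyper.n_input_features, hyper.hidden_size,
                         hyper.n_recurrent_layers, hyper.dropout,
                         rng=np.random.default_rng(0))
            net.load_state_dict(
                {k: data[k] for k in data.files
                 if not k.startswith("__")})
            scaler = Scaler(np.asarray(data["__scaler_mean__"]),
                            np.asarray(data["__scaler_std__"]))
        return cls(meta["event_type"], MarkerCombo.from_name(meta["combo"]),
                   hyper, net, scaler, meta["history"], meta["seed"])


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _stack_batch(windows: Sequence[WindowSample], scaler: Scaler
                 ) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([scaler.transform(w.features.values) for w in windows],
                 axis=1)  # (T, B, C)
    y = np.stack([w.targets for w in windows], axis=1)  # (T, B)
    return x, y


def train_detector(train_windows: Sequence[WindowSample],
                   val_windows: Sequence[WindowSample],
                   hyper: DetectorHyperParams,
                   config: TrainConfig,
                   event_type: str = "IC",
                   combo: MarkerCombo | str = "TOE|HEE",
                   verbose: bool = False) -> TrainedDetector:
    """Train a bidirectional LSTM event labeller.

    Adam at the preset learning rate, binary-weighted cross-entropy on
    the Gaussian targets, balanced group sampling of training windows,
    early stopping on validation loss with the best-validation
    parameters restored.  Fully deterministic given ``config.seed``.
    """
    if isinstance(combo, str):
        combo = MarkerCombo.from_name(combo)
    if not train_windows and config.max_epochs > 0:
        raise ValueError("empty training set")
    for w in list(train_windows) + list(val_windows):
        if w.features.n_channels != hyper.n_input_features:
            raise ValueError(
                f"window has {w.features.n_channels} channels, "
                f"model expects {hyper.n_input_features}")

    rng = np.random.default_rng(config.seed)
    net = BiLSTM(hyper.n_input_features, hyper.hidden_size,
                 hyper.n_recurrent_layers, hyper.dropout, rng=rng)
    if train_windows:
        scaler = Scaler.fit([w.features.values for w in train_windows])
    else:
        scaler = Scaler(np.zeros(hyper.n_input_features),
                        np.ones(hyper.n_input_features))
    history: list[dict[str, float]] = []
    if config.max_epochs <= 0:
        return TrainedDetector(event_type, combo, hyper, net, scaler,
                               history, config.seed)

    pos_weight = config.pos_weight
    if pos_weight is None:
        pos_weight = auto_pos_weight([w.targets for w in train_windows])

    sampler = balanced_group_sampler(train_windows, config.group_ratio, rng)
    optimizer = Adam(net.params, lr=hyper.learning_rate)
    steps_per_epoch = max(1, math.ceil(len(train_windows)
                                       / config.batch_size))

    def val_loss() -> float:
        if not val_windows:
            return float("nan")
        losses = []
        for i in range(0, len(val_windows), config.batch_size):
            x, y = _stack_batch(val_windows[i:i + config.batch_size], scaler)
            logits, _ = net.forward(x, training=False)
            loss, _ = weighted_bce_from_logits(logits, y, pos_weight)
            losses.append(loss * y.shape[1])
        return float(np.sum(losses) / len(val_windows))

    best_state = net.state_dict()
    best_val = np.inf
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        train_losses = []
        for _ in range(steps_per_epoch):
            batch = [next(sampler) for _ in range(config.batch_size)]
            x, y = _stack_batch(batch, scaler)
            logits, cache = net.forward(x, training=True, rng=rng)
            loss, dlogits = weighted_bce_from_logits(logits, y, pos_weight)
            grads = net.backward(cache, dlogits)
            clip_grad_norm(grads, config.grad_clip)
            optimizer.step(grads)
            train_losses.append(loss)
        vl = val_loss()
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(train_losses)),
                        "val_loss": vl})
        if verbose:
            print(f"epoch {epoch}: train {history[-1]['train_loss']:.4f} "
                  f"val {vl:.4f}")
        monitor = vl if np.isfinite(vl) else history[-1]["train_loss"]
        if monitor < best_val - 1e-6:
            best_val = monitor
            best_state = net.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    net.load_state_dict(best_state)
    return TrainedDetector(event_type, combo, hyper, net, scaler, history,
                           config.seed)


def predict_scores(detector: TrainedDetector, features: FeatureMatrix,
                   windowed: bool = False, window: int = 150,
                   stride: int = 75) -> np.ndarray:
    """Per-frame event scores in [0, 1] for a whole trial.

    Default is full-sequence inference (a bidirectional recurrent net
    accepts any length and avoids window-stitching artifacts); the
    sliding-window mode scores overlapping windows and averages the
    overlaps.  Deterministic: identical input gives identical output.
    """
    if features.n_channels != detector.hyper.n_input_features:
        raise ValueError(
            f"features have {features.n_channels} channels, model expects "
            f"{detector.hyper.n_input_features}")
    x = detector.scaler.transform(features.values)
    if not windowed or features.n_frames <= window:
        return detector.network.predict_proba(x)
    n = features.n_frames
    acc = np.zeros(n)
    cnt = np.zeros(n)
    starts = list(range(0, n - window + 1, stride))
    if starts[-1] != n - window:
        starts.append(n - window)
    for s in starts:
        acc[s:s + window] += detector.network.predict_proba(x[s:s + window])
        cnt[s:s + window] += 1
    return acc / cnt


# ---------------------------------------------------------------------------
# Repeated-training protocol
# ---------------------------------------------------------------------------

def aggregate_runs(per_run: Sequence[Mapping[str, float]]
                   ) -> dict[str, dict[str, float]]:
    """Mean and standard error of the mean per metric across runs.

    With a single run the SEM is undefined and reported as NaN.
    """
    if not per_run:
        raise ValueError("no runs to aggregate")
    keys = sorted({k for r in per_run for k in r})
    out: dict[str, dict[str, float]] = {}
    n = len(per_run)
    for k in keys:
        vals = np.array([r[k] for r in per_run if k in r], dtype=float)
        mean = float(np.mean(vals))
        sem = (float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
               if len(vals) > 1 else float("nan"))
        out[k] = {"mean": mean, "sem": sem, "n_runs": len(vals)}
    return out


def repeated_training_protocol(
        pool_windows: Mapping[str, Sequence[WindowSample]],
        evaluate_run: Callable[[TrainedDetector], Mapping[str, float]],
        hyper: DetectorHyperParams,
        config: TrainConfig,
        n_runs: int = 10,
        event_type: str = "IC",
        combo: MarkerCombo | str = "TOE|HEE",
) -> tuple[list[dict[str, float]], dict[str, dict[str, float]],
           list[TrainedDetector]]:
    """Train ``n_runs`` detectors on different train/validation splits.

    ``pool_windows`` maps non-test subject ids to their windows; run r
    re-splits the pool into train/validation subjects with seed
    ``config.seed + r`` (the test set, embodied by ``evaluate_run``,
    stays fixed across runs).  Returns per-run metric dicts, their
    mean +/- SEM aggregate, and the trained detectors.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    subjects = sorted(pool_windows)
    # validation share among the non-test pool
    val_share = config.fractions[1] / (config.fractions[0]
                                       + config.fractions[1])
    per_run: list[dict[str, float]] = []
    detectors: list[TrainedDetector] = []
    for r in range(n_runs):
        rng = np.random.default_rng(config.seed + r)
        order = [subjects[i] for i in rng.permutation(len(subjects))]
        n_val = max(1, int(round(val_share * len(order))))
        val_subjects = set(order[:n_val])
        train_w = [w for s in subjects if s not in val_subjects
                   for w in pool_windows[s]]
        val_w = [w for s in val_subjects for w in pool_windows[s]]
        run_cfg = replace(config, seed=config.seed + r)
        det = train_detector(train_w, val_w, hyper, run_cfg,
                             event_type=event_type, combo=combo)
        per_run.append(dict(evaluate_run(det)))
        detectors.append(det)
    return per_run, aggregate_runs(per_run), detectors
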