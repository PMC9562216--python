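"""Peak-based event extraction from score curves and the
tolerance-based evaluation protocol.

A predicted event is a local maximum of the network's score curve above
0.5 with a physiological minimum peak separation.  A true event counts
as detected when at least one prediction falls within +/-16 ms of it; a
prediction counts as a true positive when at least one true event falls
within +/-16 ms of it (coverage semantics, no one-to-one assignment).
Recall and precision are the corresponding coverage percentages;
false-alarm rate is 100 - precision, missed rate is 100 - recall.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .io import GaitEvent


@dataclass(frozen=True)
class DetectionConfig:
    peak_threshold: float = 0.5
    min_peak_separation_s: float = 0.25  # physiological step-time lower bound
    tolerance_ms: float = 16.0

    def __post_init__(self) -> None:
        if not (0.0 < self.peak_threshold < 1.0):
            raise ValueError("peak_threshold must be in (0, 1)")
        if self.min_peak_separation_s <= 0:
            raise ValueError("min_peak_separation_s must be positive")
        if self.tolerance_ms <= 0:
            raise ValueError("tolerance_ms must be positive")


def detect_events(scores: np.ndarray, frame_times: np.ndarray,
                  config: DetectionConfig = DetectionConfig(),
                  event_type: str = "IC", side: str = "R"
                  ) -> list[GaitEvent]:
    """Extract predicted events from a per-frame score curve.

    Events sit at local maxima strictly above ``peak_threshold``,
    separated by at least ``min_peak_separation_s``; a flat plateau
    yields its midpoint frame.  An empty result is valid output.
    """
    scores = np.asarray(scores, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain NaN/inf")
    if scores.size < 3:
        return []
    rate = 1.0 / np.median(np.diff(frame_times))
    distance = max(1, int(round(config.min_peak_separation_s * rate)))
    idx, props = find_peaks(scores, distance=distance, plateau_size=1)
    # plateau midpoint; strict threshold on the peak value
    mids = ((props["left_edges"] + props["right_edges"]) // 2
            if "left_edges" in props else idx)
    events = []
    for i, mid in zip(idx, mids):
        if scores[i] > config.peak_threshold:
            events.append(GaitEvent(event_type, float(frame_times[mid]),
                                    side, "predicted"))
    return sorted(events, key=lambda e: e.time_s)


# ---------------------------------------------------------------------------
# Tolerance matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Coverage match between predicted and true events of one trial."""

    n_truth: int
    n_predicted: int
    truth_detected: np.ndarray      # (n_truth,) bool
    prediction_hit: np.ndarray      # (n_predicted,) bool
    errors_ms: np.ndarray           # signed error to nearest truth, per
                                    # true-positive prediction
    tolerance_ms: float

    @property
    def n_detected(self) -> int:
        return int(self.truth_detected.sum())

    @property
    def n_true_positive(self) -> int:
        return int(self.prediction_hit.sum())


def match_events(predicted: Sequence[GaitEvent],
                 truth: Sequence[GaitEvent],
                 tolerance_ms: float = 16.0) -> MatchResult:
    """Match predictions to truth with an inclusive +/- tolerance.

    A truth event is detected iff at least one prediction lies within
    the tolerance (|dt| <= tolerance, boundary inclusive); a prediction
    is a true positive iff at least one truth lies within the tolerance.
    Signed errors (prediction minus nearest truth) are recorded per
    true-positive prediction.  Mixing event types is an error.
    """
    types = {e.event_type for e in list(predicted) + list(truth)}
    if len(types) > 1:
        raise ValueError(f"mixed event types in matching: {sorted(types)}")
    t_pred = np.array([e.time_s for e in predicted], dtype=float)
    t_true = np.array([e.time_s for e in truth], dtype=float)
    tol_s = tolerance_ms / 1000.0

    if t_pred.size and t_true.size:
        diff = t_pred[:, None] - t_true[None, :]          # (P, T)
        absd = np.abs(diff)
        truth_detected = (absd <= tol_s + 1e-12).any(axis=0)
        prediction_hit = (absd <= tol_s + 1e-12).any(axis=1)
        nearest = np.argmin(absd, axis=1)
        errors = diff[np.arange(len(t_pred)), nearest][prediction_hit]
    else:
        truth_detected = np.zeros(t_true.size, dtype=bool)
        prediction_hit = np.zeros(t_pred.size, dtype=bool)
        errors = np.empty(0)
    return MatchResult(t_true.size, t_pred.size, truth_detected,
                       prediction_hit, errors * 1000.0, tolerance_ms)


# ---------------------------------------------------------------------------
# Aggregated evaluation
# ---------------------------------------------------------------------------

@dataclass
class GroupMetrics:
    n_truth: int
    n_predicted: int
    n_detected: int
    n_true_positive: int
    errors_ms: np.ndarray

    @property
    def recall_pct(self) -> float:
        return (100.0 * self.n_detected / self.n_truth
                if self.n_truth else float("nan"))

    @property
    def precision_pct(self) -> float:
        return (100.0 * self.n_true_positive / self.n_predicted
                if self.n_predicted else float("nan"))

    @property
    def missed_pct(self) -> float:
        return 100.0 - self.recall_pct

    @property
    def false_alarm_pct(self) -> float:
        return 100.0 - self.precision_pct

    def to_dict(self) -> dict:
        return {
            "n_truth": self.n_truth,
            "n_predicted": self.n_predicted,
            "recall_pct": self.recall_pct,
            "precision_pct": self.precision_pct,
            "missed_pct": self.missed_pct,
            "false_alarm_pct": self.false_alarm_pct,
            "precision_defined": bool(self.n_predicted),
            "mean_abs_error_ms": (float(np.mean(np.abs(self.errors_ms)))
                                  if self.errors_ms.size else float("nan")),
            "trimmed_mean_95_ms": (trimmed_mean_error(
                np.abs(self.errors_ms), 0.95)
                if self.errors_ms.size else float("nan")),
            "trimmed_mean_99_ms": (trimmed_mean_error(
                np.abs(self.errors_ms), 0.99)
                if self.errors_ms.size else float("nan")),
        }


@dataclass
class EvaluationReport:
    """Recall/precision/error summary per gait group and overall."""

    overall: GroupMetrics
    per_group: dict[str, GroupMetrics]
    tolerance_ms: float

    def to_dict(self) -> dict:
        return {"tolerance_ms": self.tolerance_ms,
                "overall": self.overall.to_dict(),
                "per_group": {g: m.to_dict()
                              for g, m in self.per_group.items()}}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_csv(self, path: str | Path) -> None:
        rows = [{"group": "overall", **self.overall.to_dict()}]
        rows += [{"group": g, **m.to_dict()}
                 for g, m in sorted(self.per_group.items())]
        for r in rows:
            r.pop("precision_defined", None)
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(rows[0]))
            w.writeheader()
            w.writerows(rows)


def evaluate_detection(matches: Sequence[MatchResult],
                       group_labels: Sequence[str]) -> EvaluationReport:
    """Pool per-trial matches into group and overall coverage rates.

    recall% = 100 x detected truths / truths; precision% = 100 x
    true-positive predictions / predictions, aggregated across trials by
    pooled counts.  With zero predictions in a group the precision is
    undefined and reported as NaN with ``precision_defined`` false.
    """
    if len(matches) != len(group_labels):
        raise ValueError("one group label per match required")
    if sum(m.n_truth for m in matches) == 0:
        raise ValueError("no truth events to evaluate against")
    tols = {m.tolerance_ms for m in matches}
    if len(tols) > 1:
        raise ValueError("matches computed at differing tolerances")

    def pool(ms: Sequence[MatchResult]) -> GroupMetrics:
        errors = (np.concatenate([m.errors_ms for m in ms])
                  if ms else np.empty(0))
        return GroupMetrics(
            n_truth=sum(m.n_truth for m in ms),
            n_predicted=sum(m.n_predicted for m in ms),
            n_detected=sum(m.n_detected for m in ms),
            n_true_positive=sum(m.n_true_positive for m in ms),
            errors_ms=errors)

    per_group = {}
    for g in sorted(set(group_labels)):
        per_group[g] = pool([m for m, lab in zip(matches, group_labels)
                             if lab == g])
    return EvaluationReport(pool(list(matches)), per_group, tols.pop())


def error_percentile_curve(abs_errors_ms: Sequence[float],
                           percentiles: np.ndarray | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Percentile -> absolute-error mapping (linear-interpolation
    quantiles); nondecreasing by construction."""
    errs = np.asarray(abs_errors_ms, dtype=float)
    if errs.size == 0:
        raise ValueError("no errors supplied")
    if percentiles is None:
        percentiles = np.arange(0.0, 100.5, 0.5)
    values = np.percentile(errs, percentiles, method="linear")
    return np.asarray(percentiles, float), values


def trimmed_mean_error(abs_errors_ms: Sequence[float],
                       keep_fraction: float = 0.95) -> float:
    """Mean of the smallest ceil(keep_fraction * n) absolute errors.

    Discards the worst (1 - keep_fraction) tail; keep_fraction = 1 is
    the plain mean.
    """
    errs = np.sort(np.asarray(abs_errors_ms, dtype=float))
    if errs.size == 0:
        raise ValueError("no errors supplied")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    k = int(np.ceil(keep_fraction * errs.size))
    return float(np.mean(errs[:k]))
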