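"""Resampling, differentiation, coordinate canonicalization and feature
assembly for the event detector.

The model input is a frames x channels matrix of 3D positions and
forward-difference velocities for a chosen marker combination, computed
at 150 Hz.  Training samples are 150-frame windows cut around one
annotated event with a random integer offset in +/-30 frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ForceSignal, GaitEvent, MarkerTrajectory, Trial

#: Marker combinations evaluated in the reference protocol.
PRESET_COMBOS: dict[str, tuple[str, ...]] = {
    "HLX|HEE": ("HLX", "HEE"),
    "TOE|HEE": ("TOE", "HEE"),
    "HLX|PMT5|HEE": ("HLX", "PMT5", "HEE"),
    "TOE|PMT5|HEE": ("TOE", "PMT5", "HEE"),
    "HLX|TOE|HEE": ("HLX", "TOE", "HEE"),
}

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class MarkerCombo:
    """Ordered marker combination forming the model input."""

    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("combo must contain at least one marker")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("combo contains duplicate markers")

    @classmethod
    def from_name(cls, name: str) -> "MarkerCombo":
        if name in PRESET_COMBOS:
            return cls(PRESET_COMBOS[name])
        return cls(tuple(p for p in name.split("|") if p))

    @property
    def name(self) -> str:
        return "|".join(self.markers)

    @property
    def n_channels(self) -> int:
        return 6 * len(self.markers)

    def channel_layout(self) -> list[tuple[str, str, str]]:
        """Ordered (marker, axis, kind) per channel."""
        layout = []
        for m in self.markers:
            layout += [(m, ax, "position") for ax in AXES]
            layout += [(m, ax, "velocity") for ax in AXES]
        return layout


@dataclass
class FeatureMatrix:
    """frames x channels model input with channel layout metadata."""

    values: np.ndarray                       # (frames, channels)
    rate: float
    layout: list[tuple[str, str, str]]       # (marker, axis, kind)
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames, channels)")
        if self.values.shape[1] != len(self.layout):
            raise ValueError("channel count does not match layout")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_frames) / self.rate


@dataclass
class WindowSample:
    """Fixed-length training window centred near one annotated event."""

    features: FeatureMatrix
    targets: np.ndarray        # (frames,) Gaussian-encoded event probability
    event_type: str
    group: str                 # FF | MF | HS
    subject_id: str
    offset_frames: int

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if len(self.targets) != self.features.n_frames:
            raise ValueError("targets length != window length")


@dataclass
class Scaler:
    """Per-channel standardization statistics (training-set mean/SD)."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std

    @classmethod
    def fit(cls, matrices: Sequence[np.ndarray]) -> "Scaler":
        stacked = np.concatenate([np.asarray(m) for m in matrices], axis=0)
        mean = stacked.mean(axis=0)
        std = stacked.std(axis=0)
        std[std < 1e-12] = 1.0
        return cls(mean, std)

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(),
                           "std": self.std.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Scaler":
        d = json.loads(text)
        return cls(np.asarray(d["mean"], float), np.asarray(d["std"], float))


# ---------------------------------------------------------------------------
# Resampling and differentiation
# ---------------------------------------------------------------------------

def downsample_trial(trial: Trial, target_rate: float = 150.0) -> Trial:
    """Resample a trial onto a uniform ``target_rate`` grid.

    Integer rate ratios decimate (keep every k-th frame); fractional
    ratios interpolate linearly.  Event times are seconds and stay
    unchanged; any force trace is resampled the same way.
    """
    if target_rate > trial.rate:
        raise ValueError(
            f"target rate {target_rate} Hz exceeds trial rate {trial.rate}")
    if trial.rate == target_rate:
        return trial

    ratio = trial.rate / target_rate
    n_frames = trial.n_frames

    def resample(values: np.ndarray) -> np.ndarray:
        if abs(ratio - round(ratio)) < 1e-9:
            return values[::int(round(ratio))]
        n_out = int(np.floor((n_frames - 1) / ratio)) + 1
        t_new = np.arange(n_out) * ratio
        idx = np.arange(len(values))
        if values.ndim == 1:
            return np.interp(t_new, idx, values)
        return np.column_stack(
            [np.interp(t_new, idx, values[:, k])
             for k in range(values.shape[1])])

    markers = []
    for m in trial.markers:
        pos = m.positions.copy()
        pos[m.missing_mask] = np.nan  # occlusion propagates, never blends
        new_pos = resample(pos)
        new_missing = ~np.all(np.isfinite(new_pos), axis=1)
        markers.append(MarkerTrajectory(m.marker_id, m.side, new_pos,
                                        new_missing, target_rate))
    force = trial.force
    if force is not None:
        # force may run at its own (higher) rate; leave untouched then
        if force.rate == trial.rate:
            force = ForceSignal(resample(force.values), target_rate)
    return Trial(trial.subject_id, trial.trial_id, markers, target_rate,
                 force, list(trial.events), trial.pattern, dict(trial.meta))


def compute_velocities(positions: np.ndarray, rate: float) -> np.ndarray:
    """Forward-difference velocity: v_n = (s_{n+1} - s_n) * rate.

    The final frame is padded by replicating the penultimate velocity so
    positions and velocities share one frame grid.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        raise ValueError("need at least two frames to differentiate")
    if rate <= 0:
        raise ValueError("rate must be positive")
    v = np.diff(positions, axis=0) * rate
    return np.concatenate([v, v[-1:]], axis=0)


# ---------------------------------------------------------------------------
# Coordinate canonicalization
# ---------------------------------------------------------------------------

def canonicalize(trial: Trial) -> Trial:
    """Rotate, translate and mirror a trial into the model frame.

    The horizontal plane is rotated so the dominant progression
    direction (principal axis of the HEE horizontal displacement) points
    along +x; the first-frame mid-foot centroid is subtracted; left-foot
    markers are mirrored across the sagittal plane (y -> -y) so both
    feet share one model frame.  Idempotent.  A trial with no net
    progression (standing) is an error.
    """
    sides = sorted({m.side for m in trial.markers})
    new_markers: list[MarkerTrajectory] = []
    for side in sides:
        side_markers = [m for m in trial.markers if m.side == side]
        hee = next((m for m in side_markers if m.marker_id == "HEE"), None)
        if hee is None:
            raise ValueError(f"cannot canonicalize: no HEE marker, side {side}")
        ok = ~hee.missing_mask
        horiz = hee.positions[ok][:, :2]
        if len(horiz) < 2:
            raise ValueError("not enough observed HEE frames")
        disp = horiz - horiz.mean(axis=0)
        # principal axis of horizontal displacement
        cov = disp.T @ disp
        w, vecs = np.linalg.eigh(cov)
        axis = vecs[:, np.argmax(w)]
        net = horiz[-1] - horiz[0]
        if np.linalg.norm(net) < 1e-6:
            raise ValueError("no net progression (standing trial)")
        if np.dot(axis, net) < 0:
            axis = -axis
        c, s = axis[0], axis[1]
        rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])

        rotated = {m.marker_id: m.positions @ rot.T for m in side_markers}
        first = np.array([rotated[m.marker_id][0]
                          for m in side_markers
                          if not m.missing_mask[0]])
        origin = first.mean(axis=0) if len(first) else np.zeros(3)
        for m in side_markers:
            pos = rotated[m.marker_id] - origin
            if side == "L":
                pos = pos * np.array([1.0, -1.0, 1.0])
            new_markers.append(MarkerTrajectory(m.marker_id, m.side, pos,
                                                m.missing_mask.copy(),
                                                m.rate))
    out = Trial(trial.subject_id, trial.trial_id, new_markers, trial.rate,
                trial.force, list(trial.events), trial.pattern,
                dict(trial.meta))
    out.meta["canonicalized"] = True
    return out


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def assemble_features(trial: Trial, combo: MarkerCombo | str,
                      side: str | None = None,
                      scaler: Scaler | None = None) -> FeatureMatrix:
    """Stack positions and velocities of a marker combination.

    Channel order per marker: x,y,z position (mm), then x,y,z velocity
    (mm/s).  When a ``scaler`` is supplied the channels are z-scored
    with its (training-set) statistics; otherwise raw values are
    returned.
    """
    if isinstance(combo, str):
        combo = MarkerCombo.from_name(combo)
    if side is None:
        sides = {m.side for m in trial.markers}
        if len(sides) != 1:
            raise ValueError("trial holds both feet; specify side")
        side = sides.pop()
    cols = []
    for marker_id in combo.markers:
        m = trial.marker(marker_id, side)  # KeyError if absent
        cols.append(m.positions)
        cols.append(compute_velocities(m.positions, trial.rate))
    values = np.concatenate(cols, axis=1)
    if scaler is not None:
        values = scaler.transform(values)
    return FeatureMatrix(values, trial.rate, combo.channel_layout())


# ---------------------------------------------------------------------------
# Training windows
# ---------------------------------------------------------------------------

def extract_training_window(features: FeatureMatrix, event: GaitEvent,
                            targets: np.ndarray,
                            length_frames: int = 150,
                            max_offset: int = 30,
                            rng: np.random.Generator | None = None,
                            group: str = "", subject_id: str = ""
                            ) -> WindowSample:
    """Cut a fixed-length window around one annotated event.

    The window start is ``round(event_frame) - length/2 + delta`` with
    delta drawn uniformly from the integers [-max_offset, +max_offset].
    Windows that would overrun the trial edge are shifted inward
    (clamped) rather than zero-padded.
    """
    if features.n_frames < length_frames:
        raise ValueError(
            f"trial has {features.n_frames} frames < window {length_frames}")
    rng = rng or np.random.default_rng()
    event_frame = int(round((event.time_s - features.start_time_s)
                            * features.rate))
    delta = int(rng.integers(-max_offset, max_offset + 1))
    start = event_frame - length_frames // 2 + delta
    start = min(max(start, 0), features.n_frames - length_frames)
    stop = start + length_frames
    win = FeatureMatrix(features.values[start:stop], features.rate,
                        features.layout,
                        features.start_time_s + start / features.rate)
    return WindowSample(win, np.asarray(targets, float)[start:stop],
                        event.event_type, group, subject_id,
                        offset_frames=delta)


# ---------------------------------------------------------------------------
# IC pattern classification
# ---------------------------------------------------------------------------

def classify_ic_pattern(trial: Trial, ic_events: Sequence[GaitEvent],
                        contact_margin_mm: float = 5.0,
                        side: str | None = None) -> str:
    """Classify a trial's initial-contact pattern as HS, MF or FF.

    At each IC the heel (HEE) height is compared with the forefoot
    reference (the lower of TOE / PMT5, whichever are present): heel
    lower by more than ``contact_margin_mm`` -> heel strike (HS);
    forefoot lower by more than the margin -> forefoot contact (FF,
    toe-walking); otherwise flat/midfoot contact (MF).  The trial label
    is the majority vote over ICs; ties resolve to MF.  The default
    5 mm margin is on the order of half a marker diameter.
    """
    if not ic_events:
        raise ValueError("no IC events supplied")
    if side is None:
        sides = {m.side for m in trial.markers}
        side = ic_events[0].side if len(sides) > 1 else sides.pop()
    hee = trial.marker("HEE", side)
    forefoot = [trial.marker(mid, side) for mid in ("TOE", "PMT5")
                if trial.has_marker(mid, side)]
    if not forefoot:
        raise ValueError("need TOE or PMT5 to classify the IC pattern")

    votes: list[str] = []
    for ev in ic_events:
        frame = int(round(ev.time_s * trial.rate))
        frame = min(max(frame, 0), trial.n_frames - 1)
        z_hee = hee.positions[frame, 2]
        z_ff = min(m.positions[frame, 2] for m in forefoot)
        if z_hee < z_ff - contact_margin_mm:
            votes.append("HS")
        elif z_ff < z_hee - contact_margin_mm:
            votes.append("FF")
        else:
            votes.append("MF")
    counts = {p: votes.count(p) for p in ("HS", "MF", "FF")}
    best = max(counts.values())
    winners = [p for p, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else "MF"


def classify_ic_pattern_by_angle(trial: Trial,
                                 ic_events: Sequence[GaitEvent],
                                 hs_threshold_deg: float = 0.0,
                                 ff_threshold_deg: float = -10.0,
                                 side: str | None = None) -> str:
    """Alternative mode: classify by foot pitch angle at IC.

    The sagittal pitch is the angle of the HEE->TOE vector above the
    horizontal; dorsiflexed contact (pitch > ``hs_threshold_deg``) is
    HS, plantarflexed contact (pitch < ``ff_threshold_deg``) is FF, in
    between is MF.  Thresholds are user-supplied; the defaults are this
    package's own choice, not a published convention.
    """
    if not ic_events:
        raise ValueError("no IC events supplied")
    if side is None:
        sides = {m.side for m in trial.markers}
        side = ic_events[0].side if len(sides) > 1 else sides.pop()
    hee = trial.marker("HEE", side)
    toe = trial.marker("TOE", side)
    votes: list[str] = []
    for ev in ic_events:
        frame = min(max(int(round(ev.time_s * trial.rate)), 0),
                    trial.n_frames - 1)
        vec = toe.positions[frame] - hee.positions[frame]
        horiz = np.hypot(vec[0], vec[1])
        pitch = np.degrees(np.arctan2(vec[2], horiz))
        if pitch > hs_threshold_deg:
            votes.append("HS")
        elif pitch < ff_threshold_deg:
            votes.append("FF")
        else:
            votes.append("MF")
    counts = {p: votes.count(p) for p in ("HS", "MF", "FF")}
    best = max(counts.values())
    winners = [p for p, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else "MF"
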