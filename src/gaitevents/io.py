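"""Trial, marker, force and event containers plus readers/writers.

Trials hold the four foot markers of the Conventional Gait Model
(HEE = calcaneus, TOE = distal metatarsal head, HLX = hallux,
PMT5 = proximal fifth metatarsal) per foot side.  Ground-truth gait
events are derived from the vertical ground reaction force by
threshold crossing, or supplied as manual/synthetic annotations.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

CANONICAL_MARKERS = ("HEE", "TOE", "HLX", "PMT5")

#: Default alias table mapping lab-specific labels to (canonical, side).
#: TOE is labelled inconsistently across labs ("distal metatarsal I" vs
#: "distal second metatarsal"); both designations resolve to TOE here.
DEFAULT_ALIASES: dict[str, str] = {
    "HEE": "HEE", "HEEL": "HEE", "CAL": "HEE", "CALC": "HEE",
    "TOE": "TOE", "MT1": "TOE", "MT2": "TOE", "DMT1": "TOE", "DMT2": "TOE",
    "HLX": "HLX", "HALLUX": "HLX", "HAL": "HLX",
    "PMT5": "PMT5", "MT5": "PMT5", "VMT5": "PMT5", "P5MT": "PMT5",
}

_SIDE_PREFIX = re.compile(r"^(L|R)[\s_\-:.]?", re.IGNORECASE)


def resolve_marker_label(label: str,
                         aliases: Mapping[str, str] | None = None
                         ) -> tuple[str, str] | None:
    """Match a raw point label to ``(canonical_marker, side)``.

    Labels are matched case-insensitively; a leading L/R (optionally
    separated by ``_ - : .`` or whitespace) encodes the side.  Returns
    None when the label is not a known foot marker.
    """
    aliases = {k.upper(): v for k, v in (aliases or DEFAULT_ALIASES).items()}
    lab = label.strip().upper()
    m = _SIDE_PREFIX.match(lab)
    if not m:
        return None
    side = m.group(1).upper()
    rest = lab[m.end():]
    if rest in aliases:
        return aliases[rest], side
    return None


@dataclass
class MarkerTrajectory:
    """One marker's 3D path in the lab frame (mm)."""

    marker_id: str          # one of CANONICAL_MARKERS
    side: str               # 'L' or 'R'
    positions: np.ndarray   # (frames, 3) float, mm
    missing_mask: np.ndarray  # (frames,) bool, True = occluded/invalid
    rate: float             # Hz

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (frames, 3)")
        if len(self.positions) != len(self.missing_mask):
            raise ValueError("positions and missing_mask lengths differ")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        ok = ~self.missing_mask
        if not np.all(np.isfinite(self.positions[ok])):
            raise ValueError(
                f"non-finite coordinates on observed frames of "
                f"{self.side}{self.marker_id}")

    @property
    def n_frames(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class GaitEvent:
    """A timestamped initial contact (IC) or toe-off (TO)."""

    event_type: str  # 'IC' or 'TO'
    time_s: float    # seconds from trial start; continuous, may be off-grid
    side: str        # 'L' or 'R'
    source: str = "manual"  # force | manual | synthetic | predicted

    def __post_init__(self) -> None:
        if self.event_type not in ("IC", "TO"):
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.side not in ("L", "R"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.time_s < 0:
            raise ValueError("event time must be >= 0")
        if self.source not in ("force", "manual", "synthetic", "predicted"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class ForceSignal:
    """Vertical ground reaction force trace (N)."""

    values: np.ndarray  # (frames,) N
    rate: float         # Hz

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate


@dataclass
class Trial:
    """One subject's barefoot walking pass."""

    subject_id: str
    trial_id: str
    markers: list[MarkerTrajectory]
    rate: float
    force: ForceSignal | None = None
    events: list[GaitEvent] = field(default_factory=list)
    pattern: str | None = None  # FF | MF | HS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {m.n_frames for m in self.markers}
        if len(lengths) > 1:
            raise ValueError("marker trajectories have differing lengths")
        rates = {m.rate for m in self.markers}
        if rates and rates != {self.rate}:
            raise ValueError("marker rates differ from trial rate")
        dur = self.duration_s
        for ev in self.events:
            if ev.time_s > dur + 1e-9:
                raise ValueError(
                    f"event at {ev.time_s:.3f}s beyond trial end {dur:.3f}s")

    @property
    def n_frames(self) -> int:
        return self.markers[0].n_frames if self.markers else 0

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate if self.markers else np.inf

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def marker(self, marker_id: str, side: str | None = None
               ) -> MarkerTrajectory:
        for m in self.markers:
            if m.marker_id == marker_id and (side is None or m.side == side):
                return m
        raise KeyError(f"marker {marker_id} ({side or 'any side'}) not found")

    def has_marker(self, marker_id: str, side: str | None = None) -> bool:
        try:
            self.marker(marker_id, side)
            return True
        except KeyError:
            return False

    def events_of(self, event_type: str, side: str | None = None
                  ) -> list[GaitEvent]:
        out = [e for e in self.events
               if e.event_type == event_type
               and (side is None or e.side == side)]
        return sorted(out, key=lambda e: e.time_s)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_trial_c3d(path: str | Path, side: str = "both",
                   aliases: Mapping[str, str] | None = None,
                   subject_id: str = "", trial_id: str = "") -> Trial:
    """Read a C3D motion-capture file into a Trial.

    Point labels are matched case-insensitively against the alias table;
    frames with a negative residual (the C3D convention for an invalid /
    interpolation-failed point) are flagged in ``missing_mask``.

    ``side`` restricts the markers to L, R, or both feet.  Raises a
    FileNotFoundError / ValueError for unreadable files and a KeyError
    naming any required foot marker missing for a requested side.
    """
    from . import _c3d

    c3d = _c3d.read_c3d(Path(path))
    if side not in ("L", "R", "both"):
        raise ValueError("side must be 'L', 'R' or 'both'")
    wanted_sides = ("L", "R") if side == "both" else (side,)

    markers: list[MarkerTrajectory] = []
    for i, label in enumerate(c3d.labels):
        resolved = resolve_marker_label(label, aliases)
        if resolved is None:
            continue
        marker_id, marker_side = resolved
        if marker_side not in wanted_sides:
            continue
        pos = c3d.points[:, i, :3]
        missing = c3d.residuals[:, i] < 0
        pos = pos.copy()
        pos[missing] = np.nan
        markers.append(MarkerTrajectory(marker_id, marker_side, pos,
                                        missing, c3d.rate))

    present_sides = {m.side for m in markers}
    check_sides = wanted_sides if side != "both" else sorted(present_sides)
    if not check_sides:
        raise KeyError(f"no foot markers found in {path}")
    for s in check_sides:
        have = {m.marker_id for m in markers if m.side == s}
        absent = [m for m in CANONICAL_MARKERS if m not in have]
        if absent:
            raise KeyError(
                f"required marker(s) {', '.join(absent)} absent for side {s} "
                f"in {path}")

    return Trial(subject_id=subject_id or Path(path).stem,
                 trial_id=trial_id or Path(path).stem,
                 markers=markers, rate=c3d.rate)


def write_trial_c3d(trial: Trial, path: str | Path) -> None:
    """Write a trial's markers to a C3D file (float point data)."""
    from . import _c3d

    labels = [f"{m.side}{m.marker_id}" for m in trial.markers]
    n_frames = trial.n_frames
    points = np.zeros((n_frames, len(trial.markers), 3))
    residuals = np.zeros((n_frames, len(trial.markers)))
    for i, m in enumerate(trial.markers):
        pos = np.where(m.missing_mask[:, None], 0.0, m.positions)
        points[:, i, :] = pos
        residuals[m.missing_mask, i] = -1.0
    _c3d.write_c3d(Path(path), labels, points, residuals, trial.rate)


def read_trial_table(path: str | Path,
                     schema: Mapping[str, Sequence[str]] | None = None,
                     rate: float | None = None,
                     subject_id: str = "", trial_id: str = "") -> Trial:
    """Read a delimited marker table (CSV/TSV, TRC-like export).

    The table needs a ``time`` column plus ``<label>_x/_y/_z`` columns per
    marker, where ``<label>`` resolves through the alias table (e.g.
    ``LHEE_x``).  ``schema`` optionally maps a (side+marker) label to its
    three column names explicitly.  Blank or NaN cells mark the frame as
    missing for that marker.  A non-monotone time column is an error.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip(): c for c in df.columns}
    time_col = next((cols[c] for c in cols if c.lower() == "time"), None)
    if time_col is None:
        raise ValueError(f"{path}: no 'time' column")
    t = df[time_col].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time column not strictly increasing")
        inferred = 1.0 / np.median(dt)
        if abs(inferred - round(inferred)) < 0.01:  # undo print rounding
            inferred = float(round(inferred))
    else:
        inferred = rate or 0.0
    rate = rate or inferred
    if rate <= 0:
        raise ValueError(f"{path}: cannot infer sampling rate")

    if schema is None:
        schema = {}
        for c in cols:
            m = re.match(r"^(.+)[_ ]([xyzXYZ])$", c)
            if not m:
                continue
            schema.setdefault(m.group(1), [None, None, None])
            schema[m.group(1)]["xyz".index(m.group(2).lower())] = cols[c]

    markers: list[MarkerTrajectory] = []
    for label, xyz_cols in schema.items():
        resolved = resolve_marker_label(label)
        if resolved is None or any(c is None for c in xyz_cols):
            continue
        marker_id, marker_side = resolved
        pos = df[list(xyz_cols)].to_numpy(dtype=float)
        missing = ~np.all(np.isfinite(pos), axis=1)
        markers.append(MarkerTrajectory(marker_id, marker_side, pos,
                                        missing, rate))
    if not markers:
        raise ValueError(f"{path}: no recognizable marker columns")
    return Trial(subject_id=subject_id or Path(path).stem,
                 trial_id=trial_id or Path(path).stem,
                 markers=markers, rate=rate)


def write_trial_table(trial: Trial, path: str | Path) -> None:
    """Write markers to CSV with time + <side><marker>_x/y/z columns."""
    import pandas as pd

    data: dict[str, np.ndarray] = {"time": trial.frame_times}
    for m in trial.markers:
        pos = m.positions.copy()
        pos[m.missing_mask] = np.nan
        for ax, name in enumerate("xyz"):
            data[f"{m.side}{m.marker_id}_{name}"] = pos[:, ax]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Force-based ground truth
# ---------------------------------------------------------------------------

def extract_force_events(force: ForceSignal, threshold_n: float = 20.0,
                         side: str = "R",
                         debounce_s: float = 0.05) -> list[GaitEvent]:
    """Extract IC/TO events from a vGRF trace by threshold crossing.

    An IC is placed at each upward crossing of ``threshold_n`` (default
    20 N) and a TO at each subsequent downward crossing; crossing times
    are linearly interpolated between the bracketing samples, so events
    are continuous times rather than frame-snapped.  Crossings closer
    than ``debounce_s`` are merged to suppress chatter from force noise
    near the threshold.  A trace entirely below threshold yields an
    empty list.  NaNs in the trace are an error.
    """
    v = force.values
    if not np.all(np.isfinite(v)):
        raise ValueError("force trace contains NaN/inf")
    above = v > threshold_n
    changes = np.flatnonzero(np.diff(above.astype(np.int8)))

    crossings: list[tuple[float, bool]] = []  # (time, rising)
    for i in changes:
        rising = above[i + 1]
        # linear interpolation of the crossing instant
        frac = (threshold_n - v[i]) / (v[i + 1] - v[i])
        t = (i + frac) / force.rate
        crossings.append((t, rising))

    # debounce: drop pairs of opposite crossings closer than debounce_s
    cleaned: list[tuple[float, bool]] = []
    for t, rising in crossings:
        if cleaned and (t - cleaned[-1][0]) < debounce_s \
                and cleaned[-1][1] != rising:
            cleaned.pop()
        else:
            cleaned.append((t, rising))

    events = [GaitEvent("IC" if rising else "TO", t, side, "force")
              for t, rising in cleaned]
    return sorted(events, key=lambda e: e.time_s)


# ---------------------------------------------------------------------------
# Occlusion exclusion rule
# ---------------------------------------------------------------------------

@dataclass
class CompletenessReport:
    ok: bool
    gaps: dict[str, list[tuple[int, int]]]  # marker -> [(start, stop)] incl.

    def __str__(self) -> str:
        if self.ok:
            return "complete"
        parts = [f"{m}: " + ", ".join(f"{a}-{b}" for a, b in rr)
                 for m, rr in self.gaps.items()]
        return "missing " + "; ".join(parts)


def check_marker_completeness(trial: Trial,
                              required: Iterable[str] = CANONICAL_MARKERS,
                              span: tuple[int, int] | None = None
                              ) -> CompletenessReport:
    """Apply the occlusion exclusion rule.

    Fails when any required marker has at least one missing frame inside
    the analysis span (default: the full trial); the report lists the
    offending marker and its missing frame ranges.
    """
    lo, hi = span if span is not None else (0, trial.n_frames)
    gaps: dict[str, list[tuple[int, int]]] = {}
    for m in trial.markers:
        if m.marker_id not in required:
            continue
        miss = np.flatnonzero(m.missing_mask[lo:hi]) + lo
        if miss.size == 0:
            continue
        runs: list[tuple[int, int]] = []
        start = prev = int(miss[0])
        for f in miss[1:]:
            if f == prev + 1:
                prev = int(f)
            else:
                runs.append((start, prev))
                start = prev = int(f)
        runs.append((start, prev))
        gaps[f"{m.side}{m.marker_id}"] = runs
    return CompletenessReport(ok=not gaps, gaps=gaps)


# ---------------------------------------------------------------------------
# Event serialization
# ---------------------------------------------------------------------------

_EVENT_FIELDS = ("trial_id", "side", "event_type", "time_s", "source")


def write_events(events: Sequence[GaitEvent], path: str | Path,
                 trial_id: str = "", fmt: str | None = None) -> None:
    """Write events to CSV or JSON (lossless round trip of all fields)."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = [{"trial_id": trial_id, "side": e.side,
             "event_type": e.event_type, "time_s": repr(float(e.time_s)),
             "source": e.source} for e in events]
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_EVENT_FIELDS)
            w.writeheader()
            w.writerows(rows)
    elif fmt == "json":
        for r in rows:
            r["time_s"] = float(r["time_s"])
        path.write_text(json.dumps(rows, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_events(path: str | Path) -> list[GaitEvent]:
    """Read events written by :func:`write_events` (CSV or JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    return [GaitEvent(r["event_type"], float(r["time_s"]), r["side"],
                      r["source"]) for r in rows]


def read_events_by_trial(path: str | Path) -> dict[str, list[GaitEvent]]:
    """Read an events file grouped by its trial_id column."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    out: dict[str, list[GaitEvent]] = {}
    for r in rows:
        out.setdefault(r["trial_id"], []).append(
            GaitEvent(r["event_type"], float(r["time_s"]), r["side"],
                      r["source"]))
    return out
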