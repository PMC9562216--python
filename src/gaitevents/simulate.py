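"""Synthetic barefoot-gait simulator with exact ground truth.

Generates desk-scale walking trials for one foot in three
initial-contact patterns — heel strike (HS), flat/midfoot contact (MF)
and forefoot contact / toe-walking (FF) — with marker trajectories for
HEE, TOE, HLX and PMT5, exact IC/TO times, and a synthetic vertical
ground reaction force.  The foot is modelled as a rigid segment whose
origin translates (forward progression + swing arc) and pitches about a
pattern-dependent pivot: positive pitch dorsiflexes (toe up, heel-strike
attitude), negative pitch plantarflexes (heel up, toe-walking attitude).
Markers are rigidly attached at anatomical offsets; during stance the
foot origin is horizontally stationary, so marker speed collapses at IC
and rises again at TO — the kinematic signature the detector learns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ForceSignal, GaitEvent, MarkerTrajectory, Trial

#: Marker offsets along the foot axis (mm from heel) and mount heights
#: above the sole (mm): HEE on the calcaneus, TOE at the distal
#: metatarsal head, HLX on the hallux, PMT5 on the proximal fifth
#: metatarsal.  Lateral offsets are for a right foot; left mirrors.
MARKER_GEOMETRY = {
    #            along   lateral  height
    "HEE": (0.0, 0.0, 25.0),
    "TOE": (1.0, 0.05, 22.0),     # along/lateral as fraction of foot length
    "HLX": (1.18, 0.12, 16.0),
    "PMT5": (0.72, -0.22, 24.0),
}

#: Foot pitch keyframes (degrees) per pattern at fixed stance phases.
#: Phases: IC, foot-flat, mid-stance, heel-off, TO, mid-swing.
_PITCH_KEYS = {
    "HS": [(0.00, 12.0), (0.20, 0.0), (0.55, 0.0), (0.80, -8.0),
           (1.00, -20.0)],
    "MF": [(0.00, 0.0), (0.55, 0.0), (0.80, -8.0), (1.00, -20.0)],
    "FF": [(0.00, -18.0), (0.45, -13.0), (1.00, -24.0)],
}
_SWING_PITCH = {"HS": 12.0, "MF": 0.0, "FF": -18.0}  # attitude at next IC
_MIDSWING_PITCH = {"HS": 2.0, "MF": -3.0, "FF": -15.0}


@dataclass(frozen=True)
class SimConfig:
    pattern: str = "HS"               # HS | MF | FF
    n_strides: int = 5
    cadence_spm: float = 110.0        # steps per minute
    speed_m_s: float = 1.0
    rate_hz: float = 150.0            # 150 or 300
    noise_sd_mm: float = 0.0          # i.i.d. Gaussian coordinate noise
    foot_length_mm: float = 180.0
    marker_height_offsets_mm: tuple[float, float, float, float] = (
        0.0, 0.0, 0.0, 0.0)           # per HEE/TOE/HLX/PMT5 mount jitter
    body_weight_n: float = 400.0
    side: str = "R"
    seed: int = 0
    stance_fraction: float | None = None  # default 0.60 (HS/MF), 0.65 (FF)
    swing_clearance_mm: float = 55.0

    def __post_init__(self) -> None:
        if self.pattern not in ("HS", "MF", "FF"):
            raise ValueError(f"invalid pattern {self.pattern!r}")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if min(self.cadence_spm, self.speed_m_s, self.rate_hz) <= 0:
            raise ValueError("cadence, speed and rate must be positive")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")


def _cosine_interp(keys: list[tuple[float, float]], u: np.ndarray
                   ) -> np.ndarray:
    """Piecewise cosine (smooth-step) interpolation between keyframes."""
    out = np.empty_like(u)
    for (u0, v0), (u1, v1) in zip(keys[:-1], keys[1:]):
        sel = (u >= u0) & (u <= u1)
        s = (u[sel] - u0) / (u1 - u0)
        out[sel] = v0 + (v1 - v0) * (1.0 - np.cos(np.pi * s)) / 2.0
    out[u < keys[0][0]] = keys[0][1]
    out[u > keys[-1][0]] = keys[-1][1]
    return out


def _stance_vgrf(u: np.ndarray, bw: float) -> np.ndarray:
    """Double-bump stance vGRF envelope with steep on/off ramps.

    A 3% ramp at contact and release makes the 20 N crossings sit within
    a millisecond or two of the kinematic IC/TO, so force-derived events
    agree with the stored truth to within one frame.
    """
    keys = [(0.0, 0.0), (0.03, 1.05 * bw), (0.25, 1.2 * bw),
            (0.50, 0.75 * bw), (0.78, 1.1 * bw), (0.97, 1.0 * bw),
            (1.0, 0.0)]
    f = _cosine_interp(keys, u)
    # linear ramps at the edges so the threshold crossing is sharp
    ramp_in = u < 0.03
    f[ramp_in] = (u[ramp_in] / 0.03) * 1.05 * bw
    ramp_out = u > 0.97
    f[ramp_out] = ((1.0 - u[ramp_out]) / 0.03) * 1.0 * bw
    return f


def simulate_trial(config: SimConfig) -> Trial:
    """Simulate one barefoot walking trial with exact truth events.

    Returns a Trial whose ``events`` hold the exact IC/TO times
    (source = synthetic), whose ``pattern`` is the generating pattern,
    and whose ``force`` is the synthetic single-foot vGRF at the marker
    rate.
    """
    rng = np.random.default_rng(config.seed)
    stride_t = 2.0 * 60.0 / config.cadence_spm
    stance_frac = config.stance_fraction or (
        0.65 if config.pattern == "FF" else 0.60)
    stance_t = stance_frac * stride_t
    swing_t = stride_t - stance_t
    stride_len = config.speed_m_s * stride_t * 1000.0  # mm

    # the trial starts 85% of a swing before the first IC and ends 85%
    # of a swing after the last TO, so exactly n_strides IC/TO pairs lie
    # inside the span (no unrecorded contact enters the field of view)
    lead_in = 0.85 * swing_t
    duration = lead_in + (config.n_strides - 1) * stride_t \
        + stance_t + 0.85 * swing_t
    n_frames = int(np.floor(duration * config.rate_hz))
    t = np.arange(n_frames) / config.rate_hz

    ics = lead_in + np.arange(config.n_strides) * stride_t
    tos = ics + stance_t

    # --- foot-origin trajectory (heel point at sole level) -------------
    x = np.empty(n_frames)
    z = np.empty(n_frames)
    pitch = np.empty(n_frames)
    contact_x = np.arange(-1, config.n_strides + 1) * stride_len

    for k in range(-1, config.n_strides):
        ic_k = lead_in + k * stride_t
        to_k = ic_k + stance_t
        in_stance = (t >= ic_k) & (t < to_k)
        if np.any(in_stance):
            u = (t[in_stance] - ic_k) / stance_t
            x[in_stance] = contact_x[k + 1]
            z[in_stance] = 0.0
            pitch[in_stance] = _cosine_interp(_PITCH_KEYS[config.pattern], u)
        next_ic = ic_k + stride_t
        in_swing = (t >= to_k) & (t < next_ic)
        if np.any(in_swing):
            s = (t[in_swing] - to_k) / (next_ic - to_k)
            # smooth-step forward progression, sine-squared arc
            prog = (1.0 - np.cos(np.pi * s)) / 2.0
            x[in_swing] = contact_x[k + 1] + prog * stride_len
            z[in_swing] = config.swing_clearance_mm * np.sin(np.pi * s) ** 2
            pitch[in_swing] = _cosine_interp(
                [(0.0, _PITCH_KEYS[config.pattern][-1][1]),
                 (0.5, _MIDSWING_PITCH[config.pattern]),
                 (1.0, _SWING_PITCH[config.pattern])], s)

    theta = np.radians(pitch)
    fl = config.foot_length_mm
    # pivot: heel for dorsiflexed attitude, forefoot for plantarflexed
    pivot = np.where(theta >= 0, 0.0, fl)

    markers: list[MarkerTrajectory] = []
    height_jitter = dict(zip(("HEE", "TOE", "HLX", "PMT5"),
                             config.marker_height_offsets_mm))
    lateral_sign = 1.0 if config.side == "R" else -1.0
    for mid, (along_frac, lat_frac, height) in MARKER_GEOMETRY.items():
        along = along_frac * fl
        lat = lateral_sign * lat_frac * fl
        h = height + height_jitter[mid]
        mx = x + np.cos(theta) * (along - pivot) + pivot
        mz = z + np.sin(theta) * (along - pivot) + h
        my = np.full(n_frames, lat)
        pos = np.column_stack([mx, my, mz])
        if config.noise_sd_mm > 0:
            pos = pos + rng.normal(0.0, config.noise_sd_mm, pos.shape)
        markers.append(MarkerTrajectory(mid, config.side, pos,
                                        np.zeros(n_frames, bool),
                                        config.rate_hz))

    # --- synthetic vGRF -------------------------------------------------
    force = np.zeros(n_frames)
    for ic_k, to_k in zip(ics, tos):
        in_stance = (t >= ic_k) & (t <= to_k)
        u = (t[in_stance] - ic_k) / stance_t
        force[in_stance] = _stance_vgrf(u, config.body_weight_n)

    events = [GaitEvent("IC", float(ti), config.side, "synthetic")
              for ti in ics]
    events += [GaitEvent("TO", float(ti), config.side, "synthetic")
               for ti in tos]
    events.sort(key=lambda e: e.time_s)

    return Trial(subject_id="sim", trial_id=f"sim-{config.pattern}-"
                 f"{config.seed}",
                 markers=markers, rate=config.rate_hz,
                 force=ForceSignal(force, config.rate_hz),
                 events=events, pattern=config.pattern,
                 meta={"sim_config": {"pattern": config.pattern,
                                      "seed": config.seed,
                                      "cadence_spm": config.cadence_spm,
                                      "speed_m_s": config.speed_m_s}})


def simulate_cohort(n_subjects: int,
                    pattern_mix: dict[str, float] | None = None,
                    trials_per_subject: int = 1,
                    seed: int = 0,
                    rate_hz: float = 150.0,
                    n_strides: int = 5,
                    noise_sd_mm: float = 1.0) -> list[Trial]:
    """Simulate a cohort with subject-level gait-parameter draws.

    Patterns are allocated proportionally to ``pattern_mix`` (default
    HS:MF:FF = 4:2:1, mirroring a typical clinical case mix); each
    subject draws its own cadence, speed, foot length and marker mount
    jitter so subject-level splits are meaningful.  Deterministic per
    seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    pattern_mix = pattern_mix or {"HS": 4.0, "MF": 2.0, "FF": 1.0}
    total = sum(pattern_mix.values())
    if total <= 0:
        raise ValueError("empty pattern mix")

    # exact proportional allocation, remainders to the largest shares
    quotas = {p: n_subjects * r / total for p, r in pattern_mix.items()}
    counts = {p: int(np.floor(q)) for p, q in quotas.items()}
    remainder = n_subjects - sum(counts.values())
    for p in sorted(quotas, key=lambda p: quotas[p] - counts[p],
                    reverse=True)[:remainder]:
        counts[p] += 1
    patterns = [p for p in ("HS", "MF", "FF") for _ in range(counts.get(p, 0))]

    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for s_idx, pattern in enumerate(patterns):
        subj_rng = np.random.default_rng(rng.integers(2 ** 31))
        cadence = float(np.clip(subj_rng.normal(112.0, 10.0), 85.0, 140.0))
        speed = float(np.clip(subj_rng.normal(1.0, 0.15), 0.6, 1.5))
        foot_len = float(np.clip(subj_rng.normal(185.0, 20.0), 140.0, 240.0))
        offsets = tuple(subj_rng.normal(0.0, 2.0, size=4))
        side = "R" if subj_rng.random() < 0.5 else "L"
        subject_id = f"subj{s_idx:03d}"
        for k in range(trials_per_subject):
            cfg = SimConfig(
                pattern=pattern, n_strides=n_strides,
                cadence_spm=float(np.clip(
                    cadence + subj_rng.normal(0, 2.0), 80.0, 145.0)),
                speed_m_s=float(np.clip(
                    speed + subj_rng.normal(0, 0.05), 0.5, 1.6)),
                rate_hz=rate_hz, noise_sd_mm=noise_sd_mm,
                foot_length_mm=foot_len,
                marker_height_offsets_mm=offsets,
                body_weight_n=float(np.clip(
                    subj_rng.normal(420.0, 90.0), 200.0, 700.0)),
                side=side,
                seed=int(subj_rng.integers(2 ** 31)))
            trial = simulate_trial(cfg)
            trial.subject_id = subject_id
            trial.trial_id = f"{subject_id}-t{k}"
            trials.append(trial)
    return trials
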