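# Methods

## Problem and pipeline

Gait events segment a walking trial into cycles: initial contact (IC)
starts stance, toe-off (TO) starts swing. In clinical gait analysis
they are traditionally read from force plates (which cover only a few
steps) or annotated manually from video (slow, rater-dependent).
`gaitevents` detects them from the kinematics of four foot markers
alone, so every recorded step of a marker-based session can be used.

The pipeline is: resample marker trajectories to 150 Hz → differentiate
→ canonicalize coordinates → stack positions + velocities of a marker
combination → label each frame with an event probability using a
bidirectional LSTM → extract events as thresholded peaks → score
against ground truth with a temporal tolerance.

## Signal model

**Velocities** are forward differences, vₙ = (sₙ₊₁ − sₙ)/Δt with
Δt = 1/150 s. The difference quotient (not a smoothed derivative) is
used deliberately: the step-to-step discontinuity of foot speed at
contact is the salient signature. The last velocity frame replicates
the penultimate one so positions and velocities share one frame grid.

**Rate handling.** Integer rate ratios decimate (every k-th frame);
fractional ratios interpolate linearly onto the uniform target grid.
Event times are stored in seconds and are unaffected by resampling.

**Canonicalization** removes nuisance variation the model must not
learn: the horizontal plane is rotated so the principal axis of heel
displacement points along +x (walkway direction), the first-frame
mid-foot centroid is subtracted (lab origin), and left-foot trials are
mirrored across the sagittal plane so both feet share one model frame.
The transform is idempotent; a standing trial (no net progression) is
rejected.

**Standardization.** Channels are z-scored with training-set mean/SD
(persisted with the checkpoint). Positions are O(10³) mm while
velocities are O(10³) mm/s but differently distributed; per-channel
scaling stabilizes optimization. Constant channels keep SD 1 to avoid
division blow-ups.

## Targets

Nominal event times are uncertain at roughly the inter-rater level
(~16 ms), so events are encoded as Gaussian bumps
y(t) = exp(−(t − tₑ)²/2σ²), σ = 16 ms (configurable), truncated at 4σ,
peak-normalised to 1 — not a unit-area density, because the network
output is a sigmoid in [0, 1] and the 0.5 detection threshold presumes
order-1 peaks. Overlapping events combine by pointwise maximum, which
keeps the target in [0, 1] and preserves two distinct peaks.

## Network and training

A stack of bidirectional LSTM layers (per-direction hidden size H,
outputs concatenated to 2H, dropout between layers) feeds a per-frame
linear map and sigmoid. Forward pass, backpropagation through time,
and the Adam optimiser are implemented on NumPy arrays; the analytic
gradients are checked against central finite differences in the test
suite (relative error < 1e-4). Initialization is uniform
(−1/√H, 1/√H) with +1 forget-gate bias.

Training details:

- **Windows:** 150 frames cut around one event with an integer offset
  drawn uniformly from ±30 frames. Windows that would overrun a trial
  edge are shifted inward (clamped) rather than zero-padded — padding
  creates artificial silence the network can exploit.
- **Balanced sampling:** each draw picks the gait group (HS:MF:FF at
  4:2:1 by default) with probability proportional to its ratio, then a
  window uniformly within the group, with replacement.
- **Loss:** weighted binary cross-entropy,
  −mean[w·y·log p + (1−y)·log(1−p)], with the positive-class weight w
  computed once, dataset-level, as Σ(1−y)/Σy over the training targets
  (a scalar override is accepted). With Gaussian targets and 150-frame
  windows w is typically ≈ 25.
- **Optimisation:** Adam at the preset learning rate, batch 64, at most
  100 epochs, early stopping on validation loss with patience 10 and
  best-validation weights restored, global gradient-norm clip at 5.
  Batch size, epoch budget, patience and clipping are this package's
  choices for desk-scale data; they are exposed in `TrainConfig`.
- **Splits:** subjects (never trials or windows) are partitioned
  80/10/10; the repeated-training protocol re-splits train/validation
  with seed base+r per run r, holds the test set fixed, and reports
  each metric as mean ± SEM across runs (SEM is NaN for a single run).
- **Determinism:** one seed drives parameter init, dropout masks,
  sampling and window offsets; identical seeds reproduce identical
  histories.

Inference runs on full sequences — a bidirectional recurrent net
accepts any length, and this avoids window-stitching artifacts. A
sliding-window mode (stride 75, overlaps averaged) exists for very long
traces.

Named hyper-parameter presets cover all ten (event type × marker
combination) pairs, e.g. `IC:TOE|HEE` = 12 features / 5 layers / 256
hidden / dropout 0.3 / lr 0.001. A `fast_profile` (1 layer, 64 hidden,
no dropout, lr 0.003) supports quick experiments; it is what the test
suite trains.

## Event extraction and evaluation

Predicted events are local maxima of the score curve strictly above 0.5
with a minimum separation of 0.25 s (a physiological lower bound on
step time; configurable). Plateaus yield their midpoint frame.

Matching uses coverage semantics, not one-to-one assignment: a truth
event is *detected* iff at least one prediction lies within the
tolerance, and a prediction is a *true positive* iff at least one truth
event lies within it; the tolerance boundary is inclusive
(|Δt| ≤ 16 ms counts). Recall% and precision% are pooled counts across
trials, reported per gait group and overall; false-alarm% is exactly
100 − precision%. Signed errors (prediction minus nearest truth) feed
the percentile curve (linear-interpolation quantiles) and the trimmed
means; the k%-trimmed mean is defined as the mean of the smallest
⌈k·n⌉ absolute errors, i.e. the worst tail is discarded. With zero
predictions, precision is undefined and flagged rather than coerced.

## Force-based ground truth

IC/TO are extracted from the vertical ground reaction force at each
upward/downward crossing of 20 N, with the crossing instant linearly
interpolated between bracketing samples so events are continuous times.
Opposite crossings closer than 50 ms are merged (debounce) to suppress
chatter from force noise near the threshold. Any trial in which a
required foot marker is occluded inside the analysis span is excluded
(the completeness report lists marker and frame ranges).

## Synthetic gait simulator

The simulator is the package's controlled stand-in for clinical data —
all trajectories and events it emits are synthetic by construction.
The foot is a rigid segment: four markers at anatomical offsets
(fractions of a drawn foot length, mount heights of 16–25 mm) attached
to an origin that translates and pitches. Positive pitch = dorsiflexed
(heel-strike attitude, pivot at the heel); negative pitch =
plantarflexed (toe-walking attitude, pivot at the forefoot). Pitch
keyframes per pattern (HS: +12° at IC rolling to foot-flat then −20° at
TO; MF: flat contact; FF: −18° at IC, never flat) are interpolated with
piecewise cosines. Stance occupies 60% of the stride (65% for FF,
whose gait is typically faster-cadence with prolonged forefoot
loading); these are literature-typical values and configurable. During
stance the origin is horizontally stationary — marker speed collapses
at IC and rises at TO, which is the physical signature the detector
learns; swing advances the origin by one stride length along a
smooth-step profile with a sin² clearance arc (55 mm). Trials start
and end mid-swing so exactly n_strides IC/TO pairs lie inside the span.

The synthetic vGRF is a double-bump stance envelope (peaks 1.2 and 1.1
body weight, mid-stance valley 0.75 BW) with 3% linear on/off ramps, so
the 20 N crossings sit within ~2 ms of the kinematic IC/TO — the
pipeline's internal consistency check (force extraction reproduces
truth within one frame on noiseless trials) depends only on those
crossings, not on biofidelity of the waveform.

Observation noise is i.i.d. Gaussian per coordinate (default 1 mm for
cohorts, on the order of optical marker jitter). Cohorts allocate
patterns proportionally to the requested mix (default 4:2:1) and draw
per-subject cadence (112 ± 10 steps/min), speed (1.0 ± 0.15 m/s), foot
length (185 ± 20 mm), body weight (420 ± 90 N), side, and marker mount
jitter (SD 2 mm), so subject-level splits are meaningful.

What the simulator does **not** emulate: soft-tissue artefact and
autocorrelated marker noise, marker occlusions, stride-to-stride
timing variability within a trial, crouch or other whole-limb
pathological kinematics, double support/contralateral interference on
the force plate, assisted or shod gait. Passing tests therefore show
that the implementation is internally correct and that the
architecture can recover events from contact-like kinematic signatures
— not that clinical-grade accuracy transfers to hospital data.

## IC pattern classification

The default rule compares heel vs forefoot marker heights at each IC:
heel lower by more than a 5 mm margin → HS; a forefoot marker (TOE or
PMT5) lower by more than the margin → FF; otherwise MF; trial label by
majority vote, ties → MF. The 5 mm margin is about half a marker
diameter. An alternative mode classifies by sagittal foot pitch at IC
with user-supplied thresholds; published dorsiflexion-angle thresholds
for this grouping are not available, so the defaults there are this
package's own choice.

## Numerical and design notes

- Crossing/event times are continuous (interpolated), never snapped to
  frames, avoiding rate-dependent bias.
- The tolerance boundary is inclusive; "within ±16 ms" is read as
  |Δt| ≤ 16 ms.
- Peak threshold is strict (> 0.5), so an exactly-0.5 plateau is not an
  event.
- Checkpoints are single `.npz` files bundling weights, hyper-params,
  combo, scaler statistics, seed and a format version.
- The TOE marker is labelled inconsistently across labs (distal first
  vs second metatarsal); the alias table accepts both designations and
  is configurable per lab.
- Degenerate inputs fail loudly: standing trials, empty training sets,
  channel mismatches, NaN force traces, zero-prediction precision.

## Problem sizes used in the tests

The end-to-end check trains the small profile on ~620 windows from 70
synthetic subjects (4:2:1 mix, 1 mm noise, 5 strides each, two window
draws per event), validates on 8 subjects and evaluates on 10
stratified held-out subjects at ±16 ms tolerance; it converges in under
30 epochs. These sizes were chosen as the smallest cohort at which
subject-level splitting is still meaningful and the balanced sampler
sees every group.

## Known limitations

- Bidirectional inference needs the whole trial: not usable for
  real-time detection.
- The NumPy trainer is single-threaded; the full 5-layer × 256-hidden
  presets are practical but slow compared to GPU frameworks.
- TO detection is intrinsically harder than IC (weaker kinematic
  discontinuity); expect lower rates, as with any method of this class.
- The C3D codec covers the marker-only subset of the standard (Intel
  byte order, POINT group); analog channels and event sections in C3D
  files are ignored.
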