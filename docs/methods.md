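# Methods

This note documents the models, conventions and numerical choices behind
`armkin`, and what the synthetic test bench does and does not establish
about real motion-capture data.

## Coordinate systems and units

Positions are stored in meters in a right-handed lab frame with X
anterior, Y vertical-up and Z to the subject's right; file readers convert
from millimeters where a format stores them (TRC `Units mm`, C3D). Angles
are degrees externally and radians only transiently inside trigonometric
code. Frames are 0-based; frame windows are half-open `[start, stop)`,
while repetition segments store inclusive `[start, end]` frames because
the endpoint frame (PTA) is itself a measurement point. Occluded samples
are NaN; a sample with any non-finite coordinate is treated as fully
missing.

Left-impaired subjects are mirrored about the sagittal plane (z → −z)
before any frame construction, so a single right-side sign convention
serves the whole cohort.

## Marker model and calibration

The marker set fixes segment cluster sizes (trunk 3, acromion 3, humerus
4, forearm 4, hand 3 — 17 dynamic markers) but real placements vary by
protocol, so the package learns them rather than assuming them: the static
trial is used to express each segment's anatomical landmarks — and its own
cluster markers — in the segment's anatomical frame. The anatomical frame
of each segment is built from three landmarks by one of two recipes
(origin / long-axis point / plane point, the plane point fixing either the
anterior or the lateral direction). Dynamic segment poses are then the
least-squares rigid (Kabsch) fit of the calibrated cluster coordinates to
the observed markers, which handles partial occlusions (any ≥3 visible
cluster markers) and is noise-optimal in the isotropic case. Frames with
fewer than three visible cluster markers are invalid and propagate NaN
through the affected channels.

Marker trajectories are low-pass filtered before frame fitting
(zero-lag 4th-order Butterworth, 6 Hz default) — standard kinematic
smoothing; pass `lowpass_hz=None` to disable.

The default *placement model* (`armkin.bodymodel`) — local marker
coordinates and segment lengths (trunk 0.45 m, upper arm 0.28 m, forearm
0.25 m, hand 0.08 m, acromion cluster as a gliding 2-DoF scapula frame) —
exists for the synthetic generator; the analysis path never reads its
numbers. Its local coordinates are re-expressed so that the landmark
recipe applied to them yields the identity pose, which makes the forward
kinematics → marker synthesis → calibration → angle recovery loop close
exactly on noiseless data (a strong end-to-end correctness check).

## Joint angles

Relative segment rotations are decomposed with intrinsic Euler/Cardan
sequences following the ISB upper-limb recommendations:

| joint | reference | sequence | channels |
|---|---|---|---|
| trunk | lab | Z-X-Y | flexion(+)/extension, lateral bending, axial rotation |
| scapula | thorax | Y-X-Z | pro/retraction, medial/lateral rotation, ant/post tilt |
| shoulder | thorax | Y-X-Y | plane of elevation, elevation (negative), axial rotation |
| elbow | humerus | Z-X-Y | flexion/extension, (carrying angle, unreported), pro/supination |
| wrist | forearm | Z-X-Y | flexion/extension, ulnar/radial deviation, (axial, unreported) |

The humerus is referenced to the thorax (humerothoracic angles), the
clinical convention; its position still rides on the scapula in the
kinematic chain. For the proper (Y-X-Y) shoulder sequence the
decomposition is reported on the equivalent branch with a **negative**
middle angle, so an elevated arm reads a negative elevation — the sign
convention used in UL movement analysis. At a gimbal singularity (middle
angle at 0/180° for proper, ±90° for Cardan sequences) the third angle is
set to zero and the full twist assigned to the first angle, and the frame
is flagged; channels are unwrapped per channel (180° jump threshold)
because RMSE waveform scoring needs continuous traces.

The scapula is tracked by the acromion cluster directly, without an
additional calibration correction — documented here as the package's
default; a correction can be layered on by supplying modified landmark
locals.

## Repetition segmentation

The study events (start: hand resting on the ipsilateral knee; end: point
of task achievement) were picked manually in the original workflow; the
package implements a reproducible surrogate on the hand-centroid speed
profile:

1. coarse movement bouts where speed ≥ 5% of the recording's peak
   (minimum bout 0.15 s), with the home position taken as the median hand
   position before the first bout and a 5 cm home-zone radius;
2. a bout starting in the home zone is an outbound reach; its start is
   walked back to the last truly resting frame (speed below max(0.5% of
   peak, twice the measured rest-noise speed), capped at 1 s) and its PTA
   is the first frame of the following away-from-home dwell at which the
   hand has come to rest;
3. sub-frame refinement: the bout's supra-threshold speed samples are fit
   with the three-parameter minimum-jerk speed profile
   v(τ) = 16·v_p·τ²(1−τ)², whose onset/settle times localize the
   boundaries with sub-frame precision *independently of movement
   duration*. The refinement uses a lighter 12 Hz speed smoothing because
   heavy smoothing shifts the apparent onset by a fixed absolute time.
   Integer frame events are kept for PTA/ROM extraction; the fractional
   boundaries drive time normalization and duration.

A recording that never exceeds 0.05 m/s peak speed is reported as
containing no movement. Repetitions with any required marker occluded on
strictly more than 20% of their duration are excluded (exactly 20% is
retained — the rule is "greater than"). Selection keeps the k = 2
repetitions with the lowest occlusion fraction, ties broken by recording
id then earliest repetition — task compliance, a subjective criterion in
the original workflow, is deliberately not modeled, so selection is
deterministic and order-invariant.

## Scoring

Channels are resampled by linear interpolation onto P = 101 points of the
movement cycle (endpoint-preserving; NaN gaps inside a selected segment —
at most 20% by the filter — are bridged linearly). The AVS is the RMSE
against the reference bank; the default compares with the bank's
**point-wise mean** waveform, mirroring the Gait-Profile-Score family this
score parallels; averaging RMSEs against each reference subject
individually is available (`mode="per_subject"`, always ≥ the default by
Jensen's inequality). APS is the arithmetic mean of exactly 13 AVS —
supplying any other count is an error, not a silent renormalization.

The reference bank's cycle grid is calibrated to the event detector: a
noiseless typically-developing recording per task is segmented with the
same conventions and the mean relative start/PTA offsets define the grid
the bank waveforms are tabulated on. Without this, the boundary convention
itself would register as spurious pathology in every subject; with it, a
deviation-free simulated child scores APS ≈ 0.001°.

Spatiotemporal metrics use the centroid of the three hand markers
(robust to single-marker noise), low-pass filtered at 6 Hz before
differentiation. Duration is (end − start)/rate (fractional boundaries
when available); timing of peak velocity is expressed as % of duration;
straightness is hand-path length over the start-to-end chord and is
clamped at its theoretical minimum of 1. ROM is computed on raw
(un-normalized) segment frames so normalization cannot alter extrema.

## Statistics

* Kruskal-Wallis (tie-corrected, chi-square reference) across MACS levels;
  a sample with zero spread reports H = 0, p = 1 rather than an error.
* Post-hoc Mann-Whitney U, U = min(U₁, U₂), exact p for small tie-free
  samples, tie-corrected normal approximation otherwise.
* Holm-Bonferroni step-down: sorted p(i) vs α/(m−i+1); for the m = 3
  parameter families of one joint angle the ladder is 0.0167/0.025/0.05 at
  α = 0.05. The same correction is applied over the three pairwise MACS
  contrasts in the post-hoc family. Rejections are a prefix of the sorted
  order by construction.
* Correlations: Pearson for continuous pairs; point-biserial (Pearson on
  0/1 coding) for dichotomous variables with the normality-based biserial
  adjustment behind a flag — which clinical scales received which
  treatment is not recoverable, so the battery defaults to Pearson and
  both forms are exposed for direct use. Magnitude classification:
  <0.30 little or no, 0.30–0.50 low, 0.50–0.70 moderate, >0.70 high,
  0.90–1.00 very high (boundary 0.50 classed upward, 0.70 downward,
  matching the stated open/closed ends). The published-table convention of
  displaying only |r| ≥ 0.30 is a rendering option
  (`StatsReport.correlations_table`), never a computation change.
* Forward stepwise regression of APS on age, MACS (coded 1–3), grip-force
  ratio, strength and tone: pure forward selection by the partial-F
  (equivalently t) test at entry α = 0.05, no removal step, ties broken by
  declared predictor order, complete-case analysis. Per-step R² is
  non-decreasing by construction.

## The synthetic generator

The generator emulates the study's input stack under its stated
conditions: cohort 15/26/9 across MACS I–III, reference bank N = 20,
100 Hz, four repetitions × two recordings per task, isotropic 1 mm marker
noise. Each task is a joint-space template (rest posture with the hand
near the knee; endpoint posture per task) connected by a minimum-jerk
transition of 1.2 s for a typically-developing child; the RGV endpoint
posture reflects the cylinder at shoulder height and arm-length distance.
Pathology is injected as per-channel constant offsets (+ a small
within-cycle slope), with distally dominant base magnitudes scaled by MACS
level (factors 0.6/1.2/2.0) and inflated by the subject's grip-force
deficit; movement durations inflate with MACS (1.1/1.3/1.6) and a
mid-cycle elbow/shoulder detour (boundary-smooth sin² bump) curves the
hand path increasingly with MACS. Reference-bank inter-subject variation:
per-channel offsets (sd 2°), amplitude scaling (sd 0.06) and phase shifts
(sd 0.02 cycle). Clinical covariates derive from the grip ratio with
additive noise, keeping each scale inside its nominal range. All values
are package defaults chosen as field-typical magnitudes; they only shape
test fixtures and are configurable.

Two cohort generators exist at different levels: `simulate_cohort`
produces full marker-trajectory subjects for end-to-end pipeline runs,
while `simulate_clinical_cohort` draws covariates and APS directly from
the generative coupling (grip-only or null) for the statistics-recovery
simulations, where hundreds of replicates are needed; the marker-level
path is exercised end to end at smaller replicate counts. Determinism is
end to end: one seed reproduces byte-identical trials.

**What passing tests do and do not show.** The generator's motions are
smooth single-peak reaches with rigid segments, isotropic white marker
noise and block occlusions. Passing recovery tests therefore establishes
the correctness of the geometry, scoring and statistics code — not
robustness to soft-tissue artifact, marker mislabeling, non-minimum-jerk
or multi-peak movements, or systematic (non-zero-mean) occlusion patterns,
none of which the generator emulates. The minimum-jerk boundary
refinement, in particular, is exact on generated data by construction and
only approximate on real reaches.

## Numerical choices and degenerate inputs

* Kabsch fits guard the reflection case (det sign) and rank-deficient
  configurations; collinear clusters raise a degenerate-frame error at
  calibration.
* Euler round trips close to < 1e-9° away from gimbal; at gimbal the
  deterministic tie-break above applies.
* The occlusion boundary (exactly 20%) is retained; the filter is
  idempotent; selection is invariant to input order.
* Zero start-to-end chord makes straightness undefined (error), as does
  zero variance in a correlation input.
* Sub-2-frame segments, ≠13 AVS values, empty cohorts and 0-frame trials
  are rejected with explicit errors.

## Problem sizes

The test suite and the acceptance script run simulations at sizes chosen
to characterize each quantity well while staying desk-scale: 1000-rotation
Euler round trips, one full noisy subject (three tasks, ~1500 frames per
recording) for angle recovery, 200 replicates for the stepwise-selection
rate and 400 label-shuffled cohorts for the null rejection rate. The
cohort statistics are exercised end to end on cohorts of ~10 subjects;
the generator's defaults reproduce the full 50-subject study shape when
asked.

## Known limitations

* C3D support requires the optional `ezc3d` dependency; TRC and the
  documented CSV dialect are first-class.
* The glenohumeral center is a calibrated static landmark, not a
  functional or regression estimate.
* Scapular angles from an acromion cluster are known to drift at high
  elevation on real skin; the rigid-body simulation does not reproduce
  this artifact.
* True biserial (vs point-biserial) correlation assumes an underlying
  normal latent variable; it can exceed 1 in small samples and is clipped.
* The statistics battery treats clinical composites as continuous in the
  automated report; explicitly dichotomous designs should call
  `correlate_and_classify` with the appropriate variable type.
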