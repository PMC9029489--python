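# Methods

## Conventions and model

Orientations are unit quaternions, scalar-first (w, x, y, z), Hamilton
product, right-handed frames. A sensor/segment orientation maps local
coordinates into the global frame; the joint rotation is the child (distal)
segment's orientation expressed in the parent (proximal) frame,
`q_rel = q_parent⁻¹ q_child`. Joint angles are intrinsic (body-fixed) Euler
decompositions of `q_rel`: YXZ for elbow, neck and torso, XYZ for the
shoulder. The middle angle is confined to [−90°, 90°]; within a configurable
tolerance (default 2°) of ±90° the decomposition is numerically unstable and
samples are flagged rather than altered. All quaternion algebra is delegated
to `scipy.spatial.transform.Rotation`.

Sensor-to-segment alignment builds a right-handed orthonormal triad from a
configured superior–inferior axis: the SI axis becomes the segment's y-axis
in sensor coordinates, the x-axis is the Gram–Schmidt projection of a global
helper axis ([1,0,0], or [0,0,1] when nearly parallel to SI), and z = x × y.
The construction is deterministic, so a placement fully specifies the triad.

Derived inertial angles are sign-flipped per joint configuration (defaults
+1), unwrapped with a 180°-jump heuristic (period 360°), and shifted so the
first valid sample matches the reference system's starting value — this
absorbs static calibration offsets, which is why constant IMU mounting errors
appear only through their motion-dependent residual. Trajectories whose
anatomical-limit violations exceed a configurable fraction (default 5%) are
excluded from analysis and logged; values are never edited.

## Synchronization

The pose-transition spike is detected as the first threshold crossing
(default 100 deg/s, configurable) of the right-shoulder-flexion angular rate,
computed by central finite differences (one-sided at the ends). For
alignment the detector input is first smoothed with a short centered moving
average (default 0.15 s): measurement noise on the low-rate markerless stream
otherwise produces spurious crossings, and a symmetric window applied
identically to every system introduces no cross-system shift. The pure
derivative/threshold operations are exposed unsmoothed.

The reference and IMU systems share a hardware trigger and are treated as
synchronized; only the markerless stream is shifted, by an integer number of
samples at the common 100 Hz rate (sub-sample alignment is out of scope).
After shifting, streams are trimmed to the common overlap and the first
retained markerless sample is adjusted to the reference value. Three
level-match modes exist: `replace` (default — only the first data point is
replaced), `shift` (whole-series level shift), and `none`. `replace` is the
default because a whole-series shift would silently remove any constant
markerless bias, which is precisely one of the quantities the bias metric is
meant to expose.

Markerless resampling (30 → 100 Hz) uses polyphase band-limited conversion
with edge padding by sample replication. An endpoint-anchored linear trend is
removed before filtering and re-added on the output grid, so constants and
ramps pass through exactly (no passband ripple) and boundary transients are
suppressed. Residual interpolation error on smooth motion is below 0.05°.

## Segmentation

Object-interaction events are an input artifact (delimited text of
start/end indices on the 100 Hz reference timeline; 0-based, closed
windows). Events are validated (sorted, no overlaps, start < end) and only
the final interaction window of each trial is analyzed, which standardizes
object-position effects. Because windowing happens after alignment, the
reference markers apply to all systems.

## Statistics

RMSE and bias are the root-mean-square and signed mean of per-frame
differences (test − reference) over the analysis window; bias is the signed
mean, the only reading consistent with its role of exposing systematic
offsets. |bias| ≤ RMSE always, with equality iff differences are constant.

ICC(3,1) — two-way mixed-effects, single measurement, consistency — is
computed from the ANOVA mean squares of the complete subjects × trials
range-of-motion matrix: ICC = (BMS − EMS)/(BMS + (k−1)·EMS), with the 95% CI
from the standard F-bound construction (F = BMS/EMS on (n−1, (n−1)(k−1))
df). A zero error mean square yields ICC = 1 with a degenerate-CI flag.
Categories: weak < 0.4, moderate 0.4 ≤ ICC < 0.75, strong ≥ 0.75; the
moderate band is implemented as `< 0.75` so values such as 0.745 are not
orphaned. The implementation is cross-checked in tests against both an
inline brute-force ANOVA oracle and pingouin's ICC(C,1).

Boxplot summaries use linear-interpolation quartiles and Tukey 1.5·IQR
whiskers clipped to the data range, with outliers listed beyond them.

## Synthetic generator

Ground-truth trajectories are concatenated minimum-jerk transitions
(10τ³ − 15τ⁴ + 6τ⁵) through via points: rest (hands down) → pose transition →
per-object reach/hold/return cycles. The pose transition duration is sized
so the shoulder-flexion peak rate equals the configured spike amplitude
(minimum-jerk peak velocity = 1.875·Δ/T; default 300 deg/s). Neck and torso
DOFs carry scaled-down copies of the arm program, emulating compensatory
trunk/head motion — a fixture choice, not a biomechanical model.

Default study conditions (chosen once as the emulated recording setup):
10 subjects × 10 task archetypes × 3 trials; reference and IMU at 100 Hz,
markerless at 30 Hz. Distortions: reference white noise 0.3°; IMU static
mounting misalignment 2°, orientation noise 0.5°, drift 0.05 deg/s about a
fixed random axis per sensor; markerless constant per-DOF bias 8°, noise 3°,
lag 0.2 s, and a −15° elbow device offset that the pipeline's correction
undoes. Reliability structure: reach amplitude = task base + subject offset
(SD 8°) + trial offset (SD 1°) + per-object jitter (SD = half the trial SD),
giving a high-ICC regime by default; both SDs are configurable to produce
any variance-ratio regime. All draws flow from one seed through
per-(subject, task, trial, purpose) substreams, so output is bit-reproducible.

What the generator does **not** emulate: soft-tissue artifact, marker or
skeleton-fit error structure, occlusion dropouts, non-stationary sensor
drift, task-specific movement strategies. Passing tests therefore validate
the pipeline's algebra, recovery behavior, and statistics — not the accuracy
of any particular hardware.

## Numerical choices and degenerate inputs

Quaternions are validated to unit norm within 1e-6 and renormalized;
comparisons are sign-invariant (q ≡ −q). Resampling ratios are reduced to a
rational up/down factor (denominator ≤ 10⁴). Empty series, all-invalid
masks, mismatched stream lengths/rates, overlapping events, spike-free sync
channels, and incomplete ICC matrices all raise typed errors from a common
hierarchy; per-trial pipeline failures are logged and skipped, with the run
aborting if more than half fail.

## Problem sizes

The bundled checks run the full default study (300 trials, ~10–17 s each of
simulated motion) for the null experiment, 20 two-subject replicate studies
for the ordering check, 10,000 quaternions for round-trip bounds, and 1,000
random matrices for the ICC oracle — sizes chosen to give tight Monte-Carlo
bounds while keeping a full run in tens of seconds on one core.

## Known limitations

* Shifts are integer samples at 100 Hz; true sub-sample lags leave up to
  half a sample of residual misalignment (visible as a small RMSE floor on
  fast motion).
* The gimbal/anatomical screening replaces a visual-review step with an
  automated threshold; the default limits are deliberately generous and
  should be tightened per protocol.
* ICC is the consistency form; absolute-agreement variants are out of scope.
* No orientation estimation from raw accelerometer/gyroscope data — streams
  arrive as orientations, and reference angles are consumed as given.
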