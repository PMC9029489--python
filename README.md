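# mocapcompare

Agreement analysis across upper-limb motion-capture systems for the
prosthesis-user population: a marker-based optical reference, a body-worn
inertial (IMU) system, and a low-rate markerless (depth-camera) system record
the same standardized object-interaction tasks simultaneously, and this
package quantifies how well the two test systems reproduce the reference's
joint angles.

It is aimed at movement scientists and rehabilitation engineers who need a
tested, scriptable version of the full comparison workflow — from raw sensor
orientations to reliability tables — plus a synthetic study generator with
known injected distortions, so every stage can be validated without human
recordings.

## What it computes

**Joint angles.** Inertial sensor orientations arrive as unit quaternions
(scalar-first, Hamilton convention). For each joint the proximal and distal
sensors are paired, re-expressed in segment coordinates through a
superior–inferior placement axis (remaining axes by orthogonality), and the
relative rotation `q_rel = q_parent⁻¹ q_child` is decomposed into intrinsic
Euler angles — YXZ for elbow, neck and torso, XYZ for the shoulder, which is
unstable in YXZ near elevated arm postures. Angles are sign-flipped per
configuration, unwrapped, and initialized to the reference system's starting
values. Samples near the middle-angle singularity or outside anatomical
limits are flagged; trajectories with too many flags are excluded.

**Synchronization and segmentation.** Every trial starts with a rapid
"motor-bike" pose transition that produces a spike in the right-shoulder
flexion angular rate. Each system's spike is located by threshold crossing on
the (smoothed) angle derivative and the markerless stream — resampled from
30 Hz to the common 100 Hz by polyphase band-limited conversion — is shifted
so the spikes coincide. The markerless elbow receives a +15° correction for
the bypass prosthesis' medial device offset. Analysis is restricted to the
last object-interaction window of each trial.

**Agreement and reliability.** For each test system, joint DOF, and task:

    RMSE = sqrt( (1/n) Σᵢ (testᵢ − refᵢ)² )       bias = (1/n) Σᵢ (testᵢ − refᵢ)

plus Tukey boxplot summaries of their distributions across subjects and
trials, and trial-to-trial reliability of the range of motion via the
intraclass correlation ICC(3,1) = (BMS − EMS) / (BMS + (k−1)·EMS) with 95%
F-bound confidence intervals, classified weak (< 0.4), moderate (0.4–0.74),
or strong (≥ 0.75).

## Worked example

```python
import mocapcompare as mc

cfg = mc.SyntheticConfig(n_subjects=3, n_trials=3, tasks=("bottle", "reach"), seed=11)
trials, ledger = mc.generate_study(cfg)
report = mc.analyze_study(trials)

print(report.agreement.groupby(["system", "joint"])[["rmse_deg", "bias_deg"]]
      .median().round(2))
```

prints

```
                     rmse_deg  bias_deg
system     joint
imu        elbow         0.86     -0.05
           neck          1.03     -0.07
           shoulder      1.92     -0.25
           torso         1.01      0.07
markerless elbow         8.42      7.78
           neck          8.52      8.04
           shoulder      8.54      8.00
           torso         8.49      7.93
```

The default generator injects a constant 8° markerless bias, 3° markerless
noise and a 0.2 s lag, against small IMU mounting/noise/drift errors — and
the pipeline recovers exactly that structure: markerless medians sit at the
injected bias, IMU errors stay near zero (its static offsets are absorbed by
reference initialization, leaving drift and misalignment residuals).
`report.icc` and `mc.render_icc_table(report)` give the per-task reliability
table with CIs and strength categories; `report.write(outdir)` saves all
tables as CSV plus a deterministic JSON mirror.

The same workflow is available from the shell:

```sh
mocapcompare simulate --out study/ --subjects 3 --trials 3 --seed 11
mocapcompare run-all --in study/ --out results/
```

with stage-level commands (`derive-angles`, `align`, `segment`, `compare`,
`icc`) operating on the documented text formats.

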