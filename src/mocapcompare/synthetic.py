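"""Synthetic upper-body task trials with known injected distortions.

The generator emulates the recording conditions of a three-system
(marker-based reference, inertial, markerless) upper-limb capture study:

* Ground-truth joint-angle trajectories for all ten analyzed DOFs, built from
  concatenated minimum-jerk transitions: a hands-down rest, a rapid
  "motor-bike" start pose (whose shoulder-flexion rate spike drives
  cross-system synchronization), then a sequence of object-interaction
  reaches whose windows form the segmentation event list.
* Inertial observation: five sensor orientation streams (head, sternum,
  pelvis, upper arm, forearm) composed from the truth angles, perturbed by
  static mounting misalignment, orientation noise, and slow drift.  With all
  distortions zero, joint-angle derivation inverts this construction exactly.
* Reference observation: truth plus small white noise at 100 Hz.
* Markerless observation: truth resampled at 30 Hz, delayed by a constant
  lag, offset by per-DOF constant biases and noise; the elbow is observed
  through the bypass device's 15 deg medial offset (i.e. -15 deg), which the
  pipeline's offset correction undoes.

Reliability structure for ICC comes from a per-subject reach-amplitude offset
(between-subject SD) plus a per-trial offset (within-subject SD).

Every random draw flows from a single seed through per-(subject, task, trial)
substreams, so identical configs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError
from .kinematics import (
    ANALYZED_DOFS,
    JointAngleSeries,
    OrientationStream,
    compose_euler,
    default_joint_definitions,
    default_placements,
)
from .segment import SegmentEventSet, validate_events
from .trial import TrialRecord

#: Task archetypes: name -> (number of object interactions, reach amplitude deg)
TASK_PRESETS: dict[str, tuple[int, float]] = {
    "page_turn": (5, 30.0),
    "small_objects": (6, 35.0),
    "heavy_objects": (5, 40.0),
    "fork": (2, 35.0),
    "doorknob": (2, 45.0),
    "reach": (2, 60.0),
    "dice": (3, 40.0),
    "bottle": (2, 35.0),
    "picture": (2, 55.0),
    "block_transport": (6, 45.0),
}

#: Per-DOF motion program: (pose baseline deg, reach scale, rest value deg).
#: The arm DOFs carry the primary reach program; neck and torso carry
#: scaled-down copies emulating compensatory trunk/head motion.
DOF_PROGRAM: dict[tuple[str, str], tuple[float, float, float]] = {
    ("shoulder", "flexion_extension"): (70.0, 1.00, 0.0),
    ("shoulder", "abduction_adduction"): (25.0, 0.45, 2.0),
    ("shoulder", "rotation"): (-15.0, -0.50, 0.0),
    ("elbow", "flexion_extension"): (90.0, 0.60, 10.0),
    ("elbow", "carrying"): (5.0, 0.05, 0.0),
    ("elbow", "rotation"): (10.0, 0.20, 0.0),
    ("torso", "flexion_extension"): (5.0, 0.20, 0.0),
    ("torso", "lateral_flexion"): (-3.0, -0.12, 0.0),
    ("torso", "rotation"): (4.0, 0.15, 0.0),
    ("neck", "flexion_extension"): (-8.0, -0.18, 0.0),
    ("neck", "lateral_flexion"): (3.0, 0.10, 0.0),
    ("neck", "rotation"): (5.0, 0.12, 0.0),
}


@dataclass(frozen=True)
class ImuDistortion:
    """Inertial-system imperfections applied in the sensor frame."""

    misalignment_deg: float = 2.0  # static mounting error per sensor
    noise_sd_deg: float = 0.5  # white orientation noise
    drift_deg_per_s: float = 0.05  # slow rotation about a fixed random axis


@dataclass(frozen=True)
class MarkerlessDistortion:
    """Markerless-system imperfections applied in angle space."""

    rate: float = 30.0
    bias_deg: float | Mapping[tuple[str, str], float] = 8.0  # constant per DOF
    noise_sd_deg: float = 3.0
    lag_s: float = 0.2  # software-clock delay vs the hardware-triggered pair
    elbow_device_offset_deg: float = -15.0  # bypass medial offset as observed

    def bias_for(self, joint: str, dof: str) -> float:
        if isinstance(self.bias_deg, Mapping):
            return float(self.bias_deg.get((joint, dof), 0.0))
        return float(self.bias_deg)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator (defaults = full study)."""

    n_subjects: int = 10
    n_trials: int = 3
    tasks: tuple[str, ...] = tuple(TASK_PRESETS)
    rate: float = 100.0
    seed: int = 0
    reference_noise_sd_deg: float = 0.3
    imu: ImuDistortion = field(default_factory=ImuDistortion)
    markerless: MarkerlessDistortion = field(default_factory=MarkerlessDistortion)
    spike_peak_rate_deg_s: float = 300.0  # pose-transition peak angular rate
    pose_shoulder_flexion_deg: float = 70.0
    between_subject_rom_sd_deg: float = 8.0
    within_subject_rom_sd_deg: float = 1.0
    rest_s: float = 0.6
    settle_s: float = 0.6
    reach_s: float = 0.45
    hold_s: float = 0.30
    gap_s: float = 0.35

    def __post_init__(self):
        if self.rate <= 0 or self.markerless.rate <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if self.n_trials < 2:
            raise ConfigurationError("need n_trials >= 2 for reliability analysis")
        if self.spike_peak_rate_deg_s <= 0:
            raise ConfigurationError("spike peak rate must be positive")
        unknown = set(self.tasks) - set(TASK_PRESETS)
        if unknown:
            raise ConfigurationError(f"unknown task archetypes: {sorted(unknown)}")

    @classmethod
    def null(cls, **overrides) -> "SyntheticConfig":
        """All distortions zero except the structural markerless elbow offset."""
        defaults = dict(
            reference_noise_sd_deg=0.0,
            imu=ImuDistortion(0.0, 0.0, 0.0),
            markerless=MarkerlessDistortion(
                bias_deg=0.0, noise_sd_deg=0.0, lag_s=0.0
            ),
            between_subject_rom_sd_deg=0.0,
            within_subject_rom_sd_deg=0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruthTrial:
    """Noise-free joint-angle trajectories plus the parameters that built them."""

    subject: str
    task: str
    trial: int
    rate: float
    angles: dict[tuple[str, str], np.ndarray]  # degrees, 100 Hz
    events: SegmentEventSet
    params: dict

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.angles.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


# ---------------------------------------------------------------------------
# trajectory construction
# ---------------------------------------------------------------------------

def _minjerk_step(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Smooth 0 -> 1 transition over [t0, t1] (minimum-jerk polynomial)."""
    tau = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau * tau)


def _via_trajectory(t: np.ndarray, vias: list[tuple[float, float]]) -> np.ndarray:
    """C1 trajectory through (time, value) via points with min-jerk transitions."""
    y = np.full(t.shape, vias[0][1])
    for (ta, va), (tb, vb) in zip(vias, vias[1:]):
        if tb > ta and vb != va:
            y = y + (vb - va) * _minjerk_step(t, ta, tb)
    return y


def _trial_rng(cfg: SyntheticConfig, subject: int, task_index: int, trial: int,
               stream: int) -> np.random.Generator:
    """Deterministic substream per (subject, task, trial, purpose)."""
    return np.random.default_rng(
        [cfg.seed & 0x7FFFFFFF, subject, task_index, trial, stream]
    )


def generate_ground_truth(
    cfg: SyntheticConfig,
    subject: int = 0,
    task: str | None = None,
    trial: int = 0,
) -> GroundTruthTrial:
    """Build one trial's smooth ground-truth trajectories and event list.

    The shoulder-flexion pose transition is sized so its peak angular rate
    equals ``cfg.spike_peak_rate_deg_s`` (minimum-jerk peak velocity is
    1.875 * amplitude / duration).
    """
    task = task or cfg.tasks[0]
    if task not in TASK_PRESETS:
        raise ConfigurationError(f"unknown task archetype {task!r}")
    task_index = list(TASK_PRESETS).index(task)
    n_objects, base_amp = TASK_PRESETS[task]

    rng_subject = np.random.default_rng([cfg.seed & 0x7FFFFFFF, subject, 101])
    subj_amp = rng_subject.normal(0.0, cfg.between_subject_rom_sd_deg)
    rng_trial = _trial_rng(cfg, subject, task_index, trial, 0)
    trial_amp = rng_trial.normal(0.0, cfg.within_subject_rom_sd_deg)
    amp = base_amp + subj_amp + trial_amp

    pose_delta = cfg.pose_shoulder_flexion_deg
    t_pose = 1.875 * abs(pose_delta) / cfg.spike_peak_rate_deg_s
    if t_pose <= 0:
        raise ConfigurationError("pose transition has zero duration")

    # timeline of object interactions
    t_task_start = cfg.rest_s + t_pose + cfg.settle_s
    seg_len = cfg.reach_s + cfg.hold_s + cfg.reach_s
    events = []
    starts = []
    t_cursor = t_task_start
    for _ in range(n_objects):
        starts.append(t_cursor)
        events.append((t_cursor, t_cursor + seg_len))
        t_cursor += seg_len + cfg.gap_s
    duration = t_cursor + 0.4
    n = int(round(duration * cfg.rate)) + 1
    t = np.arange(n) / cfg.rate

    # per-object amplitude jitter (same for every DOF, scaled by its program);
    # scales with the within-subject SD so zero-variation configs are exact
    obj_jitter = rng_trial.normal(
        0.0, 0.5 * cfg.within_subject_rom_sd_deg, size=n_objects
    )

    angles: dict[tuple[str, str], np.ndarray] = {}
    for (joint, dof), (pose, scale, rest) in DOF_PROGRAM.items():
        vias: list[tuple[float, float]] = [(0.0, rest)]
        vias.append((cfg.rest_s, rest))
        vias.append((cfg.rest_s + t_pose, pose))
        for k, ts in enumerate(starts):
            peak = pose + scale * (amp + obj_jitter[k])
            vias.append((ts, pose))
            vias.append((ts + cfg.reach_s, peak))
            vias.append((ts + cfg.reach_s + cfg.hold_s, peak))
            vias.append((ts + seg_len, pose))
        angles[(joint, dof)] = _via_trajectory(t, vias)

    event_idx = [
        (int(round(s * cfg.rate)), int(round(e * cfg.rate))) for s, e in events
    ]
    return GroundTruthTrial(
        subject=f"S{subject:02d}",
        task=task,
        trial=trial,
        rate=cfg.rate,
        angles=angles,
        events=validate_events(event_idx, trial_id=f"S{subject:02d}_{task}_{trial}"),
        params={
            "amp": float(amp),
            "subject_amp_offset": float(subj_amp),
            "trial_amp_offset": float(trial_amp),
            "pose_transition_s": float(t_pose),
            "n_objects": n_objects,
        },
    )


# ---------------------------------------------------------------------------
# system observations
# ---------------------------------------------------------------------------

_JOINT_CHAIN = ("torso", "neck", "shoulder", "elbow")
_SEGMENT_OF_SENSOR = {
    "pelvis": "pelvis",
    "sternum": "sternum",
    "head": "head",
    "upper_arm": "upper_arm",
    "forearm": "forearm",
}


def _small_rotation(rng: np.random.Generator, sd_deg: float, n: int) -> Rotation:
    """n independent small random rotations with per-axis rotvec SD (degrees)."""
    rotvec = rng.normal(0.0, np.deg2rad(sd_deg), size=(n, 3))
    return Rotation.from_rotvec(rotvec)


def truth_to_sensor_streams(
    gt: GroundTruthTrial,
    cfg: SyntheticConfig,
    placements=None,
    joints=None,
) -> dict[str, OrientationStream]:
    """Compose the five sensor orientation streams from ground-truth angles.

    Segment orientations chain pelvis -> sternum -> (head, upper arm) ->
    forearm through each joint's Euler rotation; sensors observe their segment
    through the placement triad, a static mounting misalignment, white
    orientation noise, and a linear-in-time drift rotation.  With zero
    distortions the kinematics derivation inverts this mapping exactly.
    """
    placements = placements or default_placements()
    joints = joints or default_joint_definitions()
    n = gt.n_samples
    t = np.arange(n) / gt.rate
    task_index = list(TASK_PRESETS).index(gt.task)
    subject = int(gt.subject.lstrip("S"))

    joint_rot: dict[str, Rotation] = {}
    for joint in _JOINT_CHAIN:
        jd = joints[joint]
        eul = np.column_stack([gt.angles[(joint, d)] for d in jd.dof_labels])
        joint_rot[joint] = Rotation.from_quat(
            compose_euler(eul, jd.euler_order), scalar_first=True
        )

    seg: dict[str, Rotation] = {}
    seg["pelvis"] = Rotation.identity(n)
    seg["sternum"] = seg["pelvis"] * joint_rot["torso"]
    seg["head"] = seg["sternum"] * joint_rot["neck"]
    seg["upper_arm"] = seg["sternum"] * joint_rot["shoulder"]
    seg["forearm"] = seg["upper_arm"] * joint_rot["elbow"]

    streams: dict[str, OrientationStream] = {}
    for i, (sensor_id, segment) in enumerate(_SEGMENT_OF_SENSOR.items()):
        rng = _trial_rng(cfg, subject, task_index, gt.trial, 10 + i)
        r = seg[segment]
        if cfg.imu.misalignment_deg > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            mis = Rotation.from_rotvec(np.deg2rad(cfg.imu.misalignment_deg) * axis)
            r = r * mis
        if cfg.imu.drift_deg_per_s > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            drift_angle = np.deg2rad(cfg.imu.drift_deg_per_s) * t
            r = r * Rotation.from_rotvec(drift_angle[:, None] * axis[None, :])
        if cfg.imu.noise_sd_deg > 0:
            r = r * _small_rotation(rng, cfg.imu.noise_sd_deg, n)
        # sensor = segment-with-errors expressed through the inverse placement
        r_sensor = r * placements[sensor_id].rotation().inv()
        streams[sensor_id] = OrientationStream(
            sensor_id=sensor_id,
            rate=gt.rate,
            quats=r_sensor.as_quat(scalar_first=True),
        )
    return streams


def observe_reference(
    gt: GroundTruthTrial, cfg: SyntheticConfig
) -> dict[tuple[str, str], JointAngleSeries]:
    """Reference observation: truth at 100 Hz plus white angle noise."""
    task_index = list(TASK_PRESETS).index(gt.task)
    subject = int(gt.subject.lstrip("S"))
    rng = _trial_rng(cfg, subject, task_index, gt.trial, 20)
    out = {}
    for (joint, dof), v in gt.angles.items():
        noise = (
            rng.normal(0.0, cfg.reference_noise_sd_deg, size=v.shape)
            if cfg.reference_noise_sd_deg > 0
            else 0.0
        )
        out[(joint, dof)] = JointAngleSeries(
            joint=joint, dof=dof, system="reference", rate=gt.rate, values=v + noise
        )
    return out


def observe_markerless(
    gt: GroundTruthTrial, cfg: SyntheticConfig
) -> dict[tuple[str, str], JointAngleSeries]:
    """Markerless observation: 30 Hz, lagged, biased, noisy; elbow via device offset.

    The stream is sampled on its own 30 Hz clock delayed by ``lag_s`` (values
    before trial start replicate the first truth sample).  The elbow is
    observed with the bypass device's medial offset folded in, so the
    pipeline's +15 deg correction is required to undo it.
    """
    ml = cfg.markerless
    task_index = list(TASK_PRESETS).index(gt.task)
    subject = int(gt.subject.lstrip("S"))
    rng = _trial_rng(cfg, subject, task_index, gt.trial, 30)
    t_truth = np.arange(gt.n_samples) / gt.rate
    n_out = int(np.floor(t_truth[-1] * ml.rate)) + 1
    t_out = np.arange(n_out) / ml.rate
    out = {}
    for (joint, dof), v in gt.angles.items():
        sampled = np.interp(t_out - ml.lag_s, t_truth, v)
        sampled = sampled + ml.bias_for(joint, dof)
        if joint == "elbow" and dof == "flexion_extension":
            sampled = sampled + ml.elbow_device_offset_deg
        if ml.noise_sd_deg > 0:
            sampled = sampled + rng.normal(0.0, ml.noise_sd_deg, size=sampled.shape)
        out[(joint, dof)] = JointAngleSeries(
            joint=joint, dof=dof, system="markerless", rate=ml.rate, values=sampled
        )
    return out


# ---------------------------------------------------------------------------
# study assembly
# ---------------------------------------------------------------------------

def generate_trial(
    cfg: SyntheticConfig, subject: int, task: str, trial: int
) -> TrialRecord:
    """One complete synthetic trial: truth, sensors, reference, markerless."""
    gt = generate_ground_truth(cfg, subject=subject, task=task, trial=trial)
    return TrialRecord(
        subject=gt.subject,
        task=task,
        trial=trial,
        series={
            "reference": observe_reference(gt, cfg),
            "markerless": observe_markerless(gt, cfg),
        },
        sensors=truth_to_sensor_streams(gt, cfg),
        events=gt.events,
        truth={"params": gt.params, "angles": gt.angles},
    )


def generate_study(cfg: SyntheticConfig) -> tuple[list[TrialRecord], dict]:
    """Full factorial study: subjects x tasks x trials, plus a truth ledger.

    The ledger records every injected distortion and per-trial amplitude so
    recovery of lags, biases, and reliability regimes can be scored against
    known values.
    """
    trials: list[TrialRecord] = []
    ledger: dict = {
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "n_trials": cfg.n_trials,
        "tasks": list(cfg.tasks),
        "markerless_lag_s": cfg.markerless.lag_s,
        "trials": {},
    }
    for subject in range(cfg.n_subjects):
        for task in cfg.tasks:
            for trial in range(cfg.n_trials):
                rec = generate_trial(cfg, subject, task, trial)
                trials.append(rec)
                ledger["trials"][rec.trial_id] = rec.truth["params"]
    return trials, ledger
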