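"""Joint-angle derivation from paired inertial-sensor orientations.

Orientations are unit quaternions in **scalar-first** (w, x, y, z) order with
the Hamilton product and right-handed frames.  A sensor orientation maps the
sensor frame into the global frame; a joint rotation is the orientation of the
distal (child) segment expressed in the proximal (parent) segment frame.
Joint angles are intrinsic (body-fixed) Euler decompositions of that relative
rotation — YXZ for the elbow, neck and torso, XYZ for the shoulder, matching
the clinical convention of the optical reference system.

All quaternion algebra is delegated to :class:`scipy.spatial.transform.Rotation`.
Functions accept a single quaternion ``(4,)`` or a stack ``(n, 4)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    ConfigurationError,
    ConventionError,
    EmptySeriesError,
    InvalidOrientationError,
    StreamMismatchError,
)

EULER_ORDERS = ("YXZ", "XYZ")

#: Sensor placements used by the five-sensor upper-body configuration.
SENSOR_IDS = ("head", "sternum", "pelvis", "upper_arm", "forearm")

_UNIT_TOL = 1e-6


# ---------------------------------------------------------------------------
# quaternion helpers
# ---------------------------------------------------------------------------

def as_rotation(q, tol: float = _UNIT_TOL) -> Rotation:
    """Convert scalar-first quaternion array(s) to a Rotation, checking norm.

    Raises
    ------
    InvalidOrientationError
        If any quaternion norm deviates from 1 by more than ``tol``.
    """
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise InvalidOrientationError(f"expected (..., 4) quaternions, got {q.shape}")
    norms = np.linalg.norm(q, axis=-1)
    if not np.all(np.abs(norms - 1.0) <= tol):
        worst = float(np.max(np.abs(norms - 1.0)))
        raise InvalidOrientationError(
            f"quaternion norm deviates from 1 by {worst:.3g} (tol {tol:.3g})"
        )
    return Rotation.from_quat(q / norms[..., None], scalar_first=True)


def from_rotation(r: Rotation) -> np.ndarray:
    """Rotation -> scalar-first quaternion array."""
    return r.as_quat(scalar_first=True)


def quat_allclose(q1, q2, atol: float = 1e-9) -> bool:
    """Sign-invariant quaternion comparison (q and -q are the same rotation)."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    d = np.minimum(
        np.max(np.abs(q1 - q2), axis=-1),
        np.max(np.abs(q1 + q2), axis=-1),
    )
    return bool(np.all(d <= atol))


def relative_orientation(parent, child, tol: float = _UNIT_TOL) -> np.ndarray:
    """Rotation of the child frame expressed in the parent frame.

    Returns q_rel with ``parent * q_rel == child`` (Hamilton composition),
    i.e. ``q_rel = parent^{-1} * child``.
    """
    rp = as_rotation(parent, tol)
    rc = as_rotation(child, tol)
    return from_rotation(rp.inv() * rc)


def compose_euler(angles_deg, order: str) -> np.ndarray:
    """Intrinsic Euler angles (degrees) -> scalar-first quaternion(s).

    Inverse of :func:`decompose_euler`; also used by the synthetic generator
    to build segment orientations from ground-truth joint angles.
    """
    if order not in EULER_ORDERS:
        raise ConfigurationError(f"unsupported Euler order {order!r}")
    r = Rotation.from_euler(order, np.asarray(angles_deg, dtype=float), degrees=True)
    return from_rotation(r)


def decompose_euler(q, order: str, gimbal_tol_deg: float = 2.0):
    """Decompose rotation(s) into intrinsic Euler angles (degrees).

    Parameters
    ----------
    q : array-like, shape (4,) or (n, 4)
        Unit quaternion(s), scalar-first.
    order : {"YXZ", "XYZ"}
        Intrinsic (body-fixed) rotation order.
    gimbal_tol_deg : float
        Proximity tolerance to the middle-angle singularity at +/-90 deg.

    Returns
    -------
    angles : ndarray, shape (3,) or (n, 3), degrees.  The middle angle lies in
        its principal range [-90, 90].
    gimbal_flag : bool or (n,) bool — True where |middle| is within
        ``gimbal_tol_deg`` of 90 deg (decomposition numerically unstable).
    """
    if order not in EULER_ORDERS:
        raise ConfigurationError(f"unsupported Euler order {order!r}")
    r = as_rotation(q)
    with warnings.catch_warnings():
        # exact singularity handled by the gimbal flag, not scipy's warning
        warnings.filterwarnings("ignore", message="Gimbal lock detected")
        angles = r.as_euler(order, degrees=True)
    middle = np.asarray(angles)[..., 1]
    flag = np.abs(np.abs(middle) - 90.0) <= gimbal_tol_deg
    return angles, flag


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class OrientationStream:
    """Uniformly sampled orientation stream for one body-worn sensor."""

    sensor_id: str
    rate: float
    quats: np.ndarray  # (n, 4) scalar-first
    t0: float = 0.0

    def __post_init__(self):
        self.quats = np.atleast_2d(np.asarray(self.quats, dtype=float))
        if self.quats.size == 0:
            raise InvalidOrientationError("orientation stream must be non-empty")
        if self.rate <= 0:
            raise ConfigurationError("stream rate must be positive")
        norms = np.linalg.norm(self.quats, axis=-1)
        if not np.all(np.abs(norms - 1.0) <= _UNIT_TOL):
            raise InvalidOrientationError(
                f"non-unit quaternion in stream {self.sensor_id!r}"
            )
        self.quats = self.quats / norms[:, None]

    def __len__(self) -> int:
        return self.quats.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate


@dataclass
class SensorPlacement:
    """Fixed mapping from a sensor's axes to its body segment's axes.

    ``si_axis`` is the segment's superior-inferior direction expressed in
    sensor coordinates; the two remaining segment axes are completed through
    orthogonality (deterministic Gram-Schmidt against a global helper axis),
    forming a right-handed orthonormal triad.
    """

    sensor_id: str
    segment: str
    si_axis: Sequence[float] = (0.0, 1.0, 0.0)

    def rotation(self) -> Rotation:
        """Constant rotation mapping segment coordinates to sensor coordinates."""
        y = np.asarray(self.si_axis, dtype=float)
        n = np.linalg.norm(y)
        if n < 1e-8:
            raise ConfigurationError(
                f"degenerate si_axis for sensor {self.sensor_id!r}"
            )
        y = y / n
        helper = np.array([1.0, 0.0, 0.0])
        if abs(y @ helper) > 0.9:
            helper = np.array([0.0, 0.0, 1.0])
        x = helper - (helper @ y) * y
        x = x / np.linalg.norm(x)
        z = np.cross(x, y)
        mat = np.column_stack([x, y, z])
        return Rotation.from_matrix(mat)


@dataclass
class JointDefinition:
    """Pairing of proximal/distal sensors and the joint's angle conventions."""

    joint: str
    parent_sensor: str
    child_sensor: str
    euler_order: str
    dof_labels: tuple[str, str, str]
    sign_flips: tuple[int, int, int] = (1, 1, 1)
    anatomical_limits: tuple[tuple[float, float], ...] = (
        (-180.0, 180.0),
        (-90.0, 90.0),
        (-180.0, 180.0),
    )

    def __post_init__(self):
        if self.parent_sensor == self.child_sensor:
            raise ConfigurationError("parent and child sensors must differ")
        if self.euler_order not in EULER_ORDERS:
            raise ConfigurationError(f"unsupported Euler order {self.euler_order!r}")
        for lo, hi in self.anatomical_limits:
            if not lo < hi:
                raise ConfigurationError("anatomical limits must satisfy min < max")

    def limits_for(self, dof: str) -> tuple[float, float]:
        return self.anatomical_limits[self.dof_labels.index(dof)]


@dataclass
class JointAngleSeries:
    """One joint DOF's angle trajectory in degrees for one capture system."""

    joint: str
    dof: str
    system: str  # reference | imu | markerless
    rate: float
    values: np.ndarray
    quality_mask: np.ndarray | None = None
    t0: float = 0.0
    excluded: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.rate <= 0:
            raise ConfigurationError("series rate must be positive")
        if self.quality_mask is None:
            self.quality_mask = np.ones(len(self.values), dtype=bool)
        else:
            self.quality_mask = np.asarray(self.quality_mask, dtype=bool).ravel()
            if self.quality_mask.shape != self.values.shape:
                raise ConfigurationError("quality_mask length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate

    def valid_values(self) -> np.ndarray:
        return self.values[self.quality_mask]

    def with_values(self, values, **changes) -> "JointAngleSeries":
        return replace(self, values=np.asarray(values, dtype=float), **changes)


# ---------------------------------------------------------------------------
# default joint set (right upper limb + trunk, five-sensor configuration)
# ---------------------------------------------------------------------------

def default_joint_definitions() -> dict[str, JointDefinition]:
    """Joint definitions for the elbow/shoulder/neck/torso configuration.

    The shoulder uses the XYZ order (the YXZ decomposition is numerically
    unstable near the elevated arm postures these tasks produce); all other
    joints use YXZ.  Sign flips default to +1 and are configurable.
    """
    return {
        "elbow": JointDefinition(
            joint="elbow",
            parent_sensor="upper_arm",
            child_sensor="forearm",
            euler_order="YXZ",
            dof_labels=("flexion_extension", "carrying", "rotation"),
            anatomical_limits=((-10.0, 160.0), (-45.0, 45.0), (-120.0, 120.0)),
        ),
        "shoulder": JointDefinition(
            joint="shoulder",
            parent_sensor="sternum",
            child_sensor="upper_arm",
            euler_order="XYZ",
            dof_labels=("flexion_extension", "abduction_adduction", "rotation"),
            anatomical_limits=((-90.0, 185.0), (-88.0, 88.0), (-120.0, 120.0)),
        ),
        "neck": JointDefinition(
            joint="neck",
            parent_sensor="sternum",
            child_sensor="head",
            euler_order="YXZ",
            dof_labels=("flexion_extension", "lateral_flexion", "rotation"),
            anatomical_limits=((-80.0, 80.0), (-60.0, 60.0), (-90.0, 90.0)),
        ),
        "torso": JointDefinition(
            joint="torso",
            parent_sensor="pelvis",
            child_sensor="sternum",
            euler_order="YXZ",
            dof_labels=("flexion_extension", "lateral_flexion", "rotation"),
            anatomical_limits=((-70.0, 90.0), (-60.0, 60.0), (-80.0, 80.0)),
        ),
    }


#: The ten joint DOFs entering the agreement analysis.
ANALYZED_DOFS: tuple[tuple[str, str], ...] = (
    ("elbow", "flexion_extension"),
    ("shoulder", "flexion_extension"),
    ("shoulder", "abduction_adduction"),
    ("shoulder", "rotation"),
    ("torso", "flexion_extension"),
    ("torso", "lateral_flexion"),
    ("torso", "rotation"),
    ("neck", "flexion_extension"),
    ("neck", "lateral_flexion"),
    ("neck", "rotation"),
)


def default_placements() -> dict[str, SensorPlacement]:
    """Identity placements: sensor y-axis along the segment's SI direction."""
    segments = {
        "head": "head",
        "sternum": "thorax",
        "pelvis": "pelvis",
        "upper_arm": "upper_arm",
        "forearm": "forearm",
    }
    return {
        sid: SensorPlacement(sensor_id=sid, segment=seg)
        for sid, seg in segments.items()
    }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def align_sensor_to_segment(
    stream: OrientationStream, placement: SensorPlacement
) -> OrientationStream:
    """Re-express a sensor orientation stream in body-segment coordinates.

    Each sample is composed on the right with the constant segment->sensor
    rotation built from the placement's superior-inferior axis.
    """
    if placement.sensor_id != stream.sensor_id:
        raise ConfigurationError(
            f"placement {placement.sensor_id!r} does not match stream "
            f"{stream.sensor_id!r}"
        )
    r_align = placement.rotation()
    r = as_rotation(stream.quats)
    return OrientationStream(
        sensor_id=stream.sensor_id,
        rate=stream.rate,
        quats=from_rotation(r * r_align),
        t0=stream.t0,
    )


def unwrap_degrees(values: np.ndarray) -> np.ndarray:
    """Remove +/-180 deg discontinuities (jump heuristic, 360 deg period)."""
    return np.unwrap(np.asarray(values, dtype=float), period=360.0)


def derive_joint_angles(
    parent: OrientationStream,
    child: OrientationStream,
    jd: JointDefinition,
    reference_initial: Sequence[float] = (0.0, 0.0, 0.0),
    gimbal_tol_deg: float = 2.0,
    system: str = "imu",
) -> tuple[JointAngleSeries, JointAngleSeries, JointAngleSeries]:
    """Derive the three joint DOF trajectories from aligned sensor streams.

    Per sample the relative orientation (child in the parent frame) is
    decomposed by the joint's Euler order; each DOF is sign-flipped per
    ``jd.sign_flips``, unwrapped, then shifted by a constant so its first
    valid sample equals ``reference_initial`` for that DOF (initialization to
    the reference system's starting values absorbs static calibration offsets).
    Samples within gimbal proximity are flagged invalid, not altered.
    """
    if parent.rate != child.rate:
        raise StreamMismatchError(
            f"rate mismatch: {parent.rate} Hz vs {child.rate} Hz"
        )
    if len(parent) != len(child):
        raise StreamMismatchError(
            f"length mismatch: {len(parent)} vs {len(child)} samples"
        )
    q_rel = relative_orientation(parent.quats, child.quats)
    angles, gflag = decompose_euler(q_rel, jd.euler_order, gimbal_tol_deg)
    angles = np.atleast_2d(angles)
    gflag = np.atleast_1d(gflag)
    mask = ~gflag
    if not mask.any():
        raise EmptySeriesError(
            f"all samples of joint {jd.joint!r} are gimbal-proximate"
        )
    first = int(np.argmax(mask))

    out = []
    for k, dof in enumerate(jd.dof_labels):
        v = jd.sign_flips[k] * angles[:, k]
        v = unwrap_degrees(v)
        v = v + (float(reference_initial[k]) - v[first])
        out.append(
            JointAngleSeries(
                joint=jd.joint,
                dof=dof,
                system=system,
                rate=parent.rate,
                values=v,
                quality_mask=mask.copy(),
                t0=parent.t0,
            )
        )
    return tuple(out)


def flag_gimbal_anomalies(
    series: JointAngleSeries,
    limits: tuple[float, float],
    exclusion_threshold: float = 0.05,
) -> JointAngleSeries:
    """Invalidate samples violating anatomical limits; exclude bad trajectories.

    Samples outside ``[min, max]`` get ``quality_mask = False``.  If the
    invalid fraction (over the whole trajectory) exceeds
    ``exclusion_threshold`` the series is marked excluded-from-analysis.
    Stored values are never modified.
    """
    lo, hi = limits
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ConfigurationError("anatomical limits must be finite")
    bad = (series.values < lo) | (series.values > hi)
    mask = series.quality_mask & ~bad
    invalid_frac = 1.0 - mask.mean() if len(series) else 0.0
    return replace(
        series,
        values=series.values.copy(),
        quality_mask=mask,
        excluded=bool(invalid_frac > exclusion_threshold),
    )


def rezero(series: JointAngleSeries, reference_initial: float) -> JointAngleSeries:
    """Shift a series by a constant so its first valid sample equals the target."""
    if not series.quality_mask.any():
        raise EmptySeriesError("cannot re-zero a series with no valid samples")
    first = int(np.argmax(series.quality_mask))
    shift = float(reference_initial) - series.values[first]
    return series.with_values(series.values + shift)


def apply_elbow_offset(
    series: JointAngleSeries, offset: float = 15.0
) -> JointAngleSeries:
    """Add the terminal-device medial-offset correction to a markerless elbow angle.

    The markerless tracker follows the anatomical forearm rather than the
    bypass-mounted device, which sits at a 15 deg medial offset; the correction
    shifts every sample by ``+offset``.
    """
    if series.joint != "elbow" or series.system != "markerless":
        raise ConventionError(
            "device offset applies only to markerless elbow series, got "
            f"{series.system!r} {series.joint!r}"
        )
    return series.with_values(series.values + float(offset))
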