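"""Multi-rate stream synchronization via the start-pose derivative spike.

Every trial begins with the hands at the sides followed by a rapid transition
into a "motor-bike" pose; the transition produces a large, predictable spike
in the right-shoulder flexion angular rate.  Each system's spike is located by
threshold crossing on the joint-angle derivative and the (software-clocked)
markerless stream is shifted so the spikes coincide.  The reference and IMU
streams share a hardware trigger and are treated as already synchronized.

Shifts are integer samples at the common 100 Hz rate; the markerless stream is
resampled to that rate (polyphase band-limited conversion) before alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import resample_poly

from .errors import EmptySeriesError, SpikeNotFoundError, SyncError
from .kinematics import JointAngleSeries
from .trial import TrialRecord

#: Default spike threshold on the shoulder-flexion derivative, deg/s.
DEFAULT_SPIKE_THRESHOLD = 100.0

#: Channel used for spike detection.
SYNC_CHANNEL = ("shoulder", "flexion_extension")


@dataclass(frozen=True)
class SyncResult:
    """Outcome of one trial's cross-system alignment."""

    detected_index_per_system: dict[str, int]
    applied_shift: dict[str, float]  # seconds, per system
    threshold: float  # deg/s


def angle_derivative(series: JointAngleSeries) -> JointAngleSeries:
    """Finite-difference angular rate in deg/s (central; one-sided at ends)."""
    if len(series) < 2:
        raise EmptySeriesError("derivative requires at least 2 samples")
    d = np.gradient(series.values) * series.rate
    return replace(series, values=d, quality_mask=series.quality_mask.copy())


def detect_pose_spike(derivative, threshold: float) -> int:
    """Index of the first derivative sample exceeding ``threshold`` (deg/s).

    ``derivative`` may be a :class:`JointAngleSeries` or a plain array.
    """
    if threshold <= 0:
        raise SyncError("spike threshold must be positive")
    values = derivative.values if isinstance(derivative, JointAngleSeries) else derivative
    values = np.asarray(values, dtype=float)
    above = np.flatnonzero(values > threshold)
    if above.size == 0:
        raise SpikeNotFoundError(
            f"no derivative sample exceeds {threshold} deg/s "
            f"(max {values.max():.1f})"
        )
    return int(above[0])


def _rate_fraction(target_rate: float, rate: float) -> Fraction:
    return (
        Fraction(target_rate).limit_denominator(10_000)
        / Fraction(rate).limit_denominator(10_000)
    )


def resample_series(series: JointAngleSeries, target_rate: float) -> JointAngleSeries:
    """Band-limited rate conversion spanning the same time interval.

    Uses polyphase resampling with edge padding by sample replication to
    suppress filter transients at the boundaries.  The quality mask is
    carried over by nearest-neighbour interpolation.
    """
    if target_rate <= 0:
        raise SyncError("target rate must be positive")
    if len(series) == 0:
        raise EmptySeriesError("cannot resample an empty series")
    if target_rate == series.rate:
        return replace(
            series, values=series.values.copy(), quality_mask=series.quality_mask.copy()
        )
    frac = _rate_fraction(target_rate, series.rate)
    up, down = frac.numerator, frac.denominator
    n = len(series)
    n_out = int(np.ceil(n * up / down))

    # Remove an endpoint-anchored linear trend so the polyphase filter sees a
    # signal that vanishes at the boundaries: constants/lines pass through
    # exactly (no passband ripple) and edge transients are suppressed.
    t_in = np.arange(n) / series.rate
    t_out = np.arange(n_out) / target_rate
    if n > 1:
        slope = (series.values[-1] - series.values[0]) / t_in[-1]
    else:
        slope = 0.0
    trend_in = series.values[0] + slope * t_in
    resid = series.values - trend_in

    pad = 8 * down  # input samples; multiple of down so offset maps cleanly
    x = np.pad(resid, pad, mode="edge")
    y = resample_poly(x, up, down)
    off = pad * up // down
    values = y[off : off + n_out] + series.values[0] + slope * t_out

    mask = np.interp(t_out, t_in, series.quality_mask.astype(float)) > 0.5
    return replace(series, rate=float(target_rate), values=values, quality_mask=mask)


def _smoothed_derivative(series: JointAngleSeries, smooth_s: float) -> JointAngleSeries:
    """Derivative of a centered moving-average of the angle (detector input).

    Measurement noise on a low-rate markerless stream can produce spurious
    threshold crossings in the raw finite-difference rate; a short symmetric
    smoothing window (applied identically to every system, so it introduces no
    cross-system shift) suppresses them while leaving the sustained pose-
    transition spike intact.
    """
    if smooth_s <= 0:
        return angle_derivative(series)
    window = max(1, int(round(smooth_s * series.rate)))
    smoothed = uniform_filter1d(series.values, size=window, mode="nearest")
    return angle_derivative(replace(series, values=smoothed))


def align_trial(
    trial: TrialRecord,
    sync_channel: tuple[str, str] = SYNC_CHANNEL,
    threshold: float = DEFAULT_SPIKE_THRESHOLD,
    level_match: str = "replace",
    verify_hardware_sync: bool = False,
    detector_smooth_s: float = 0.15,
) -> tuple[TrialRecord, SyncResult]:
    """Shift streams so the detected start-pose spikes coincide across systems.

    All systems must already share the common rate (markerless resampled to
    100 Hz).  Only the markerless stream is shifted by default; the reference
    and IMU systems share a hardware trigger (set ``verify_hardware_sync`` to
    also report their spike offset).  After shifting, streams are trimmed to
    the common overlap and the markerless first retained sample is
    level-matched to the reference:

    - ``"replace"`` (default): only the first markerless data point is set to
      the reference value, the literal start-point adjustment;
    - ``"shift"``: the whole markerless series is level-shifted (note this
      removes any constant markerless bias);
    - ``"none"``: no level adjustment.

    Raises
    ------
    SyncError
        If the spike cannot be found in a required system.
    """
    if level_match not in ("replace", "shift", "none"):
        raise SyncError(f"unknown level_match mode {level_match!r}")
    if "reference" not in trial.series:
        raise SyncError("trial has no reference system")
    rates = {s.rate for chans in trial.series.values() for s in chans.values()}
    if len(rates) != 1:
        raise SyncError(f"systems not on a common rate: {sorted(rates)}")
    rate = rates.pop()

    detected: dict[str, int] = {}
    for system, chans in trial.series.items():
        if sync_channel not in chans:
            raise SyncError(f"system {system!r} lacks sync channel {sync_channel}")
        try:
            detected[system] = detect_pose_spike(
                _smoothed_derivative(chans[sync_channel], detector_smooth_s), threshold
            )
        except SpikeNotFoundError as exc:
            raise SyncError(f"spike not found in system {system!r}: {exc}") from exc

    ref_idx = detected["reference"]
    offsets = {system: 0 for system in trial.series}
    if "markerless" in detected:
        offsets["markerless"] = detected["markerless"] - ref_idx
    if verify_hardware_sync and "imu" in detected:
        offsets["imu"] = detected["imu"] - ref_idx

    # Positive offset: that system's spike occurs later -> drop its head
    # samples.  Negative: trim the other systems instead.
    head_trim = max(0, -min(offsets.values()))
    starts = {system: offsets[system] + head_trim for system in trial.series}
    lengths = {
        system: min(len(s) for s in chans.values())
        for system, chans in trial.series.items()
    }
    n_common = min(lengths[system] - starts[system] for system in trial.series)
    if n_common < 2:
        raise SyncError("no usable overlap after alignment")

    ref_first = {
        ch: s.values[starts["reference"]]
        for ch, s in trial.series["reference"].items()
    }

    def shift_crop(system, ch, s):
        a = starts[system]
        values = s.values[a : a + n_common].copy()
        mask = s.quality_mask[a : a + n_common].copy()
        if system == "markerless" and ch in ref_first:
            if level_match == "replace":
                values[0] = ref_first[ch]
            elif level_match == "shift":
                values = values + (ref_first[ch] - values[0])
        return replace(s, values=values, quality_mask=mask, t0=s.t0 + a / s.rate)

    aligned = trial.map_series(shift_crop)
    if trial.events is not None:
        aligned.events = trial.events.shifted(-starts["reference"], n_common)

    result = SyncResult(
        detected_index_per_system=detected,
        applied_shift={system: offsets[system] / rate for system in trial.series},
        threshold=float(threshold),
    )
    return aligned, result
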