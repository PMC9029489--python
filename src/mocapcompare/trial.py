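"""Per-trial container bundling the three systems' streams and events."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Any

from .kinematics import JointAngleSeries, OrientationStream

if TYPE_CHECKING:  # pragma: no cover
    from .segment import SegmentEventSet

#: Channel key: (joint, dof)
Channel = tuple[str, str]


@dataclass
class TrialRecord:
    """One subject x task x trial bundle of per-system joint-angle series.

    ``series`` maps system name ("reference" | "imu" | "markerless") to a
    mapping of (joint, dof) channels.  ``sensors`` holds the raw inertial
    orientation streams (before joint-angle derivation).  ``events`` are
    object-interaction windows on the reference 100 Hz timeline.  ``truth``
    optionally records the generating parameters of a synthetic trial.
    """

    subject: str
    task: str
    trial: int
    series: dict[str, dict[Channel, JointAngleSeries]] = field(default_factory=dict)
    sensors: dict[str, OrientationStream] = field(default_factory=dict)
    events: "SegmentEventSet | None" = None
    truth: dict[str, Any] | None = None

    @property
    def trial_id(self) -> str:
        return f"{self.subject}_{self.task}_{self.trial}"

    def systems(self) -> list[str]:
        return list(self.series)

    def channel(self, system: str, joint: str, dof: str) -> JointAngleSeries:
        return self.series[system][(joint, dof)]

    def map_series(self, fn) -> "TrialRecord":
        """Return a copy with ``fn(system, channel, series)`` applied to every series."""
        new = {
            system: {ch: fn(system, ch, s) for ch, s in chans.items()}
            for system, chans in self.series.items()
        }
        return replace(self, series=new)
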