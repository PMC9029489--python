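"""Object-interaction segmentation: event validation and last-segment windowing.

Trials are manually segmented into object interactions (approach -> release).
Only the final interaction of each trial enters the agreement analysis, which
standardizes object location effects across subjects.  Event indices live on
the common 100 Hz reference timeline and are applied identically to every
system (the systems are aligned before windowing).  Indices are 0-based and
windows are closed on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import EventValidationError
from .trial import TrialRecord


@dataclass(frozen=True)
class SegmentEventSet:
    """Validated, ordered object-interaction windows for one trial."""

    trial_id: str
    segments: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.segments)

    def shifted(self, offset: int, n_samples: int | None = None) -> "SegmentEventSet":
        """Shift all windows by ``offset`` samples, dropping any that fall
        outside ``[0, n_samples)`` after the shift."""
        out = []
        for s, e in self.segments:
            s, e = s + offset, e + offset
            if s < 0:
                continue
            if n_samples is not None and e >= n_samples:
                continue
            out.append((s, e))
        return SegmentEventSet(self.trial_id, tuple(out))


def validate_events(
    raw: Iterable[Sequence[int]], trial_id: str = "trial"
) -> SegmentEventSet:
    """Sort and validate (start, end) index pairs.

    Raises
    ------
    EventValidationError
        If any pair has start >= end, a negative start, or overlaps its
        neighbour (windows are closed, so touching endpoints overlap).
    """
    pairs = sorted((int(s), int(e)) for s, e in raw)
    for s, e in pairs:
        if s < 0:
            raise EventValidationError(f"negative start index in pair ({s}, {e})")
        if s >= e:
            raise EventValidationError(f"inverted or empty pair ({s}, {e})")
    for (s0, e0), (s1, e1) in zip(pairs, pairs[1:]):
        if s1 <= e0:
            raise EventValidationError(
                f"overlapping segments ({s0}, {e0}) and ({s1}, {e1})"
            )
    return SegmentEventSet(trial_id=trial_id, segments=tuple(pairs))


def last_segment_window(trial: TrialRecord, events: SegmentEventSet) -> TrialRecord:
    """Crop every per-system series to the final object-interaction window.

    The reference system's segmentation markers are applied to all systems,
    which is valid once the streams are aligned on a common timeline.
    """
    if len(events) == 0:
        raise EventValidationError(f"no segments for trial {events.trial_id!r}")
    start, end = events.segments[-1]

    def crop(system, ch, s):
        if end >= len(s):
            raise EventValidationError(
                f"segment end {end} out of bounds for {system} {ch} "
                f"(length {len(s)})"
            )
        return replace(
            s,
            values=s.values[start : end + 1].copy(),
            quality_mask=s.quality_mask[start : end + 1].copy(),
            t0=s.t0 + start / s.rate,
        )

    cropped = trial.map_series(crop)
    cropped.events = SegmentEventSet(events.trial_id, ((0, end - start),))
    return cropped
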