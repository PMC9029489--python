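"""Exception hierarchy for the analysis pipeline.

Every error raised intentionally by this package derives from
:class:`MocapError`, so callers can distinguish pipeline failures from
programming errors.
"""


class MocapError(Exception):
    """Base class for all errors raised by mocapcompare."""


class InvalidOrientationError(MocapError):
    """A quaternion input deviates from unit norm beyond tolerance."""


class ConfigurationError(MocapError):
    """A placement, joint definition, or generator config is invalid."""


class StreamMismatchError(MocapError):
    """Paired orientation streams disagree in rate or length."""


class EmptySeriesError(MocapError):
    """An operation requiring valid samples received none."""


class ConventionError(MocapError):
    """A convention correction was applied to the wrong series kind."""


class SpikeNotFoundError(MocapError):
    """No derivative sample exceeded the synchronization threshold."""


class SyncError(MocapError):
    """Cross-system alignment failed (e.g. spike missing in one system)."""


class EventValidationError(MocapError):
    """A segmentation event list is malformed (overlap, inverted pair)."""


class IncompleteMatrixError(MocapError):
    """A subjects-by-trials matrix has missing cells; ICC needs it complete."""
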