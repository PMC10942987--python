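"""Exception hierarchy.

Every error raised by this package derives from :class:`VasomotionError`,
so callers can catch the whole family with one clause while still treating
each condition as a plain ``ValueError``.
"""


class VasomotionError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(VasomotionError, ValueError):
    """A synthetic-data spec violates its invariants."""


class TraceTooShortError(VasomotionError, ValueError):
    """A trace has fewer samples than the operation's window requires."""


class NoPeakError(VasomotionError, ValueError):
    """An intensity profile is flat: no peak above the background."""


class UnboundedProfileError(VasomotionError, ValueError):
    """The half-height crossing falls outside the sampled profile."""


class TraceRejectedError(VasomotionError, ValueError):
    """Too many frames of a kymograph failed width measurement."""


class DegenerateStreakError(VasomotionError, ValueError):
    """A streak annotation spans zero scan lines (undefined slope)."""


class LengthMismatchError(VasomotionError, ValueError):
    """A per-frame indicator does not match the expected record length."""


class OutOfBoundsError(VasomotionError, ValueError):
    """A path or ROI coordinate falls outside the image."""
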