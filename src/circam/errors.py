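"""Exception taxonomy for circam.

All library errors derive from :class:`CircamError` so callers (and the CLI,
which maps them to exit code 1) can catch one base class. Domain errors also
derive from :class:`ValueError` to behave naturally for library users.
"""


class CircamError(Exception):
    """Base class for all circam errors."""


class DomainError(CircamError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class OutsideFieldError(CircamError, ValueError):
    """A direction or image point lies outside the lens field of view."""


class NoSuitableFormatError(CircamError, LookupError):
    """No catalog sensor format is large enough for the required diagonal."""


class FovNotReachableError(CircamError, ValueError):
    """The requested field of view exceeds the model's maximum."""


class DegenerateGeometryError(CircamError, ValueError):
    """Scene/camera geometry is degenerate (e.g. camera on the table plane)."""


class CalibrationError(CircamError, ValueError):
    """Calibration cannot proceed (too few or degenerate correspondences)."""


class PackingError(CircamError, RuntimeError):
    """Non-overlapping item placement failed within the attempt budget."""
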