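"""Error types raised by the measurement pipeline.

All inherit from :class:`RvgeomError` so callers (and ``measure_bifurcation``,
which converts them into per-record flags) can catch the whole family.
"""


class RvgeomError(Exception):
    """Base class for all rvgeom errors."""


class OutOfBoundsError(RvgeomError):
    """A sampling rectangle exits the image bounds."""


class MeasurementFailureError(RvgeomError):
    """No usable vessel cross-section could be found in a profile."""


class ContrastPolarityError(RvgeomError):
    """The profile shows a bright vessel where a dark one was expected."""


class DegenerateAnnotationError(RvgeomError):
    """Annotation geometry is degenerate (e.g. zero-length centerline vector)."""


class DomainError(RvgeomError):
    """An input violates a mathematical domain requirement (e.g. width <= 0)."""
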