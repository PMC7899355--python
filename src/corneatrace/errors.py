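"""Exception hierarchy.

All errors derive from :class:`CorneaTraceError` so callers can catch the
package's failures in one clause; per-eye batch processing maps them to
machine-readable reason codes.
"""


class CorneaTraceError(Exception):
    """Base class for all corneatrace errors."""

    #: short machine-readable code used in batch logs
    reason = "error"


class SurfaceExtentError(CorneaTraceError, ValueError):
    """Radial height lies beyond the geometric extent of a conic surface."""

    reason = "extent"


class RayMissError(CorneaTraceError):
    """A ray has no intersection with the physical branch of a surface."""

    reason = "miss"


class TotalInternalReflectionError(CorneaTraceError):
    """Snell's law has no real refracted solution (|n1/n2 sin i| > 1)."""

    reason = "tir"


class NoFocusError(CorneaTraceError):
    """The exit bundle is (nearly) collimated; no focus can be bracketed."""

    reason = "no-focus"


class InvalidPlaneError(CorneaTraceError, ValueError):
    """Candidate evaluation plane lies inside or before the cornea."""

    reason = "invalid-plane"


class FitError(CorneaTraceError):
    """Least-squares fit failed (rank-deficient design or empty input)."""

    reason = "fit"


class FormatError(CorneaTraceError, ValueError):
    """CSV input is missing required columns or is empty."""

    reason = "format"


class SamplingError(CorneaTraceError):
    """Truncated-normal rejection sampling acceptance rate too low."""

    reason = "sampling"
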