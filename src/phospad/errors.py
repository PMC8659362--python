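"""Exception hierarchy shared across the package."""


class PhospadError(Exception):
    """Base class for all package-specific errors."""


class LayoutValidationError(PhospadError, ValueError):
    """A device layout (or device code) violates a structural invariant."""


class GeometryError(PhospadError, ValueError):
    """Requested rendering geometry cannot hold the device layout."""


class DetectionError(PhospadError, RuntimeError):
    """Fewer circular zones were detected in an image than the layout requires."""

    def __init__(self, found: int, required: int, message: str | None = None):
        self.found = found
        self.required = required
        super().__init__(
            message
            or f"detected {found} circular zones, layout requires {required}"
        )


class AlignmentError(PhospadError, RuntimeError):
    """Layout-to-image registration residual exceeded the allowed threshold."""


class InsufficientDataError(PhospadError, ValueError):
    """Too few observations for the requested fit or test."""


class OutOfRangeError(PhospadError, ValueError):
    """A reading falls outside the calibrated response range (no extrapolation)."""
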