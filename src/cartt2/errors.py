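"""Exception types shared across the package."""


class CartT2Error(Exception):
    """Base class for package errors."""


class InvalidParameterError(CartT2Error, ValueError):
    """A physical or statistical parameter is outside its valid domain."""


class InvalidGeometryError(CartT2Error, ValueError):
    """A phantom or segmentation geometry violates its invariants."""


class InsufficientDataError(CartT2Error, ValueError):
    """Too few observations for the requested fit or test."""


class MissingBoundaryError(CartT2Error, ValueError):
    """A cartilage plate lacks bone-interface or surface labels."""


class MissingLandmarkError(CartT2Error, ValueError):
    """A femoral plate lacks the trochlear-notch landmark needed for the ROI."""


class MissingPlateError(CartT2Error, ValueError):
    """A knee-level aggregate was requested with plates absent."""


class UndefinedEffectError(CartT2Error, ZeroDivisionError):
    """Effect size undefined (zero pooled SD with unequal means)."""


class ValidationError(CartT2Error, ValueError):
    """Input files or tables violate the declared schemas."""
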