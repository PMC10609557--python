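"""Exception and warning types shared across the package."""


class AunpHsabError(Exception):
    """Base class for all package errors."""


class InvalidInputError(AunpHsabError, ValueError):
    """Raised when input data violate a documented invariant."""


class ConfigurationError(AunpHsabError):
    """Raised when an operation needs parameters that were never supplied
    (e.g. a finite-radius evaluation on an uncalibrated surface)."""


class CalibrationError(AunpHsabError):
    """Raised when a calibration system is singular or yields unphysical
    parameters; the message names the offending references."""


class NonPositiveHardnessWarning(UserWarning):
    """Emitted when a finite-difference hardness comes out <= 0 (physically
    unusual but not fatal)."""
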