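"""Exception hierarchy.

Every error raised by the package derives from :class:`PinoquantError`, so
callers can catch one type at a pipeline boundary while the CLI maps them to
a nonzero exit status with a readable message.
"""


class PinoquantError(Exception):
    """Base class for all package errors."""


class InputError(PinoquantError):
    """A required input (file, channel, annotation) is missing."""


class FormatError(PinoquantError):
    """An input file exists but cannot be parsed as the expected format."""


class OutputError(PinoquantError):
    """An output path cannot be written."""


class ValidationError(PinoquantError):
    """A value violates a documented invariant (bounds, sign, shape)."""


class ConfigurationError(PinoquantError):
    """An analysis configuration is inconsistent or incomplete."""


class GenerationError(PinoquantError):
    """The synthetic-scene generator could not satisfy the requested layout."""


class SegmentationError(PinoquantError):
    """Thresholding/labeling failed (e.g. Otsu on a constant image)."""


class ContourError(PinoquantError):
    """A closed membrane contour could not be traced for a structure."""


class EligibilityError(PinoquantError):
    """A structure fails an inclusion rule (e.g. macropinosome too small)."""


class UndefinedStatisticError(PinoquantError):
    """A statistic is undefined for the given input (zero mean, constant channel)."""


class NormalizationError(PinoquantError):
    """A normalizing denominator is zero or invalid."""


class BackgroundError(PinoquantError):
    """No valid cytoplasmic-background region could be placed."""
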