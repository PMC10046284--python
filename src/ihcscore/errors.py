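"""Exception hierarchy for the scoring pipeline.

Every error raised by this package derives from :class:`IHCScoreError` so
callers can catch pipeline failures without masking programming errors.
"""


class IHCScoreError(Exception):
    """Base class for all ihcscore errors."""


class InvalidParameterError(IHCScoreError, ValueError):
    """A configuration value is outside its legal range."""


class SingularStainMatrixError(IHCScoreError, ValueError):
    """Stain vectors are collinear; the unmixing matrix does not exist."""


class AnnotationSchemaError(IHCScoreError, ValueError):
    """An annotation file violates the expected GeoJSON schema."""


class GeometryError(IHCScoreError, ValueError):
    """A polygon is degenerate, self-intersecting, or otherwise unusable."""


class OverlappingROIError(GeometryError):
    """Tumor and background masks overlap after rasterization."""


class EmptyROIError(IHCScoreError, ValueError):
    """A region of interest contains no pixels."""


class UndefinedTBRError(IHCScoreError, ZeroDivisionError):
    """Background mean intensity is zero; the ratio is undefined."""


class StateError(IHCScoreError, RuntimeError):
    """An operation was applied in the wrong pipeline state (e.g. double inversion)."""


class DegenerateTestError(IHCScoreError, ValueError):
    """A t-test cannot be computed because the variance term is zero."""


class SampleSizeError(IHCScoreError, ValueError):
    """Too few observations for the requested statistical test."""


class CalibrationError(IHCScoreError, ValueError):
    """Root-finding for a phantom parameter failed or the target is unattainable."""


class PhantomSpecError(IHCScoreError, ValueError):
    """A synthetic-slide specification is internally inconsistent."""


class PairingError(IHCScoreError, ValueError):
    """Image and annotation files cannot be matched one-to-one by sample id."""
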