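"""Exception hierarchy for nestrhythm.

All package errors derive from :class:`NestRhythmError` so callers can catch
pipeline failures with one clause while still distinguishing bad input files
(:class:`AnnotationFormatError`), invalid data (:class:`ValidationError`),
bad configuration (:class:`ConfigurationError`) and numerical failures
(:class:`FitError`).
"""


class NestRhythmError(Exception):
    """Base class for all nestrhythm errors."""


class AnnotationFormatError(NestRhythmError):
    """An input table does not have the expected columns or dialect."""


class ValidationError(NestRhythmError):
    """Annotation data violates an invariant (ordering, overlap, sign)."""


class ConfigurationError(NestRhythmError):
    """A configuration value (e.g. a context mapping) is missing or invalid."""


class GenerationError(NestRhythmError):
    """The synthetic generator could not satisfy a gap-threshold band."""


class InsufficientDataError(NestRhythmError):
    """Too few observations for the requested computation."""


class FitError(NestRhythmError):
    """A statistical model could not be fitted (degenerate data)."""


class UsageError(NestRhythmError):
    """An operation was called with incompatible objects (e.g. an LRT on
    models fitted to different data)."""
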