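"""Exception hierarchy shared across the pipeline.

Every error raised by the package derives from :class:`ScreenError`, so
callers can catch a single base class at pipeline boundaries while still
distinguishing failure modes in tests and logs.
"""


class ScreenError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(ScreenError):
    """Input table is structurally invalid (missing column, empty file, ...)."""


class ParseError(ScreenError):
    """A cell could not be parsed (e.g. non-numeric expression value)."""


class VocabularyError(ScreenError):
    """A token falls outside the controlled vocabulary (readout, treatment, role)."""


class InsufficientCurveError(ScreenError):
    """Too few (or degenerate) dilution points to fit a standard curve."""


class DegenerateConditionError(ScreenError):
    """A readout-condition column has zero spread (or too few values) for z-scoring."""


class UndefinedWindowError(ScreenError):
    """Z'-factor is undefined because control group means coincide."""


class InsufficientReplicationError(ScreenError):
    """Fewer than two plates/replicates available for a group comparison."""


class CannotTrainError(ScreenError):
    """Not enough complete expression profiles to train a self-organizing map."""


class ShapeError(ScreenError):
    """Dimensionality mismatch between data and a trained model."""


class ConfigError(ScreenError):
    """Invalid simulation or pipeline configuration."""
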