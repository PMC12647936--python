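"""Exception hierarchy.

Every error raised by this package derives from :class:`MasegcError` so callers
can catch one base class at pipeline boundaries.
"""


class MasegcError(Exception):
    """Base class for all package errors."""


class FormatError(MasegcError):
    """Malformed input file (duplicate ids, bad header, ...)."""


class ParseError(FormatError):
    """A cell could not be parsed; message carries row/column coordinates."""


class AlignmentError(MasegcError):
    """Sample alignment across modalities failed (empty intersection, one class)."""


class ConfigError(MasegcError):
    """Invalid configuration (out-of-range rate, unknown key, bad constraint)."""


class PreprocessError(MasegcError):
    """Filtering/imputation/scaling/screening failure."""


class ResamplingError(MasegcError):
    """SMOTE / Tomek-link parameter or state error."""


class DimensionError(MasegcError):
    """Matrix shape mismatch in the neural components or predictors."""


class TrainingError(MasegcError):
    """Optimization diverged (NaN loss); carries the loss trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class FoldPlanError(MasegcError):
    """Cross-validation plan violates partition or stratification constraints."""


class PipelineError(MasegcError):
    """A pipeline stage failed; message names the stage."""
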