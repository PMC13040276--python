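"""Exception hierarchy.

All package errors derive from :class:`EmbryoEvalError` so callers can catch
one base class; the leaf classes distinguish parameter misuse, empty or
degenerate inputs, and malformed data files.
"""


class EmbryoEvalError(Exception):
    """Base class for all errors raised by embryoeval."""


class ParameterError(EmbryoEvalError, ValueError):
    """An argument is outside its valid domain (e.g. a probability > 1)."""


class EmptyInputError(EmbryoEvalError, ValueError):
    """An operation received no rows/frames to work on."""


class DegenerateTableError(EmbryoEvalError, ValueError):
    """A statistic is undefined on the given table (e.g. zero chance variance)."""


class InsufficientDataError(EmbryoEvalError, ValueError):
    """Too few observations for the requested computation."""


class ShapeMismatchError(EmbryoEvalError, ValueError):
    """Two rasters/masks that must share dimensions do not."""


class StageParseError(EmbryoEvalError, ValueError):
    """A stage label is not one of the recognised names or codes."""


class DataError(EmbryoEvalError, ValueError):
    """A data file violates the expected schema; message carries line numbers."""
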