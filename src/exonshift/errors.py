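"""Exception hierarchy used across the pipeline.

All pipeline-raised errors derive from :class:`ExonShiftError` so callers
(notably the CLI) can distinguish validation problems (exit code 2) from
unexpected runtime failures (exit code 3).
"""


class ExonShiftError(Exception):
    """Base class for all errors raised by exonshift."""


class ValidationError(ExonShiftError, ValueError):
    """Input violates a structural invariant (duplicate ids, unknown region, ...)."""


class ParseError(ValidationError):
    """A file could not be parsed; message names the offending line/cell."""


class DomainError(ExonShiftError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class DegenerateInputError(ExonShiftError, ValueError):
    """Input is structurally valid but degenerate (e.g. constant matrix)."""


class InsufficientDataError(ExonShiftError, ValueError):
    """Too few observations to carry out the requested computation."""
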