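"""Exception hierarchy.

All package-specific failures derive from :class:`DegconcordError` so
callers can catch one type at the pipeline boundary.
"""

from __future__ import annotations


class DegconcordError(Exception):
    """Base class for all errors raised by this package."""


class AnnotationError(DegconcordError):
    """Malformed or inconsistent human-gene annotation input."""


class DEGTableError(DegconcordError):
    """Malformed animal DEG table input."""


class ZeroLogFoldChangeError(DegconcordError):
    """A record with log2fc == 0 was encountered under the ERROR policy."""


class UndefinedMarginError(DegconcordError):
    """A 2x2 test was requested on a table with an empty row or column."""


class StageError(DegconcordError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
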