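"""Exception hierarchy.

All errors derive from :class:`EarforceError` so callers can catch the
package's failures with one clause; each also derives from ``ValueError``
to behave sensibly for callers that don't know this package.
"""


class EarforceError(ValueError):
    """Base class for all errors raised by this package."""


class RangeError(EarforceError):
    """A scalar input lies outside its physically valid range."""


class ParseError(EarforceError):
    """A run CSV or session manifest could not be parsed or validated."""


class ExtractionError(EarforceError):
    """A 2 s press window could not be extracted from a longer trace."""


class DegenerateInputError(EarforceError):
    """An input has no variance (or a control channel is perfectly
    collinear), so a correlation or regression slope is undefined."""


class InsufficientDataError(EarforceError):
    """Too few values to compute the requested summary."""
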