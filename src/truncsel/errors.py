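"""Exception hierarchy for truncsel.

All exceptions derive from :class:`TruncselError` so callers can catch the
package's failures with a single except clause.  ``InvalidInputError`` maps to
CLI exit code 2, ``SolverError`` to exit code 3.
"""


class TruncselError(Exception):
    """Base class for all truncsel errors."""


class InvalidInputError(TruncselError, ValueError):
    """A parameter is outside its valid domain or inputs are inconsistent."""


class DegenerateSelectionError(TruncselError):
    """The selected fraction is empty (or numerically zero), so post-selection
    quantities such as the set composition are undefined."""


class SolverError(TruncselError):
    """A root-finder or optimizer failed to converge; the message carries the
    bracket/iteration diagnostics."""


class UndefinedRatioError(TruncselError):
    """A relative-improvement ratio is undefined because its baseline response
    is zero or negative (the denominator changes sign)."""
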