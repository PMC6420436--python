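"""Exception hierarchy for repmod.

All errors raised by the library derive from :class:`RepmodError` so callers
(and the CLI) can distinguish analysis failures from programming errors.
"""


class RepmodError(Exception):
    """Base class for all repmod errors."""


class FileFormatError(RepmodError):
    """The input file could not be parsed as CSV."""


class MissingColumnError(RepmodError):
    """A named column is absent from the input file."""


class SampleSizeError(RepmodError):
    """Too few complete rows to fit the requested model (need n >= q + 2)."""


class SingularDesignError(RepmodError):
    """The design matrix is rank deficient (collinear or constant columns)."""


class CenteringError(RepmodError):
    """Mean-centering was requested for a categorical column."""


class ProbeError(RepmodError):
    """Invalid probing request (bad points, wrong tuple length, ...)."""


class JNNotApplicableError(RepmodError):
    """The Johnson-Neyman procedure cannot be applied to this model/moderator."""
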