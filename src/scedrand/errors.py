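"""Exception hierarchy for scedrand.

Every error raised by the library derives from :class:`SCEDError`, so callers
(including the CLI) can catch one type and report a readable message.
"""


class SCEDError(Exception):
    """Base class for all scedrand errors."""


class FormatError(SCEDError):
    """Input file does not follow the expected dialect (columns, line count)."""


class ParseError(SCEDError):
    """A value inside an otherwise well-formed file could not be parsed."""


class EmptyInputError(FormatError):
    """A file contained no usable rows/values."""


class DesignError(SCEDError):
    """A randomization scheme is infeasible or admits no divisions."""


class DesignInconsistencyError(DesignError):
    """The actually realised division is not a member of the admissible set."""


class UnsupportedDesignError(SCEDError):
    """The requested design/label pattern is outside the supported schemes."""


class DegenerateDivisionError(SCEDError):
    """A candidate division yields an all-constant predicted response.

    The test engine catches this and conventions the statistic to 0 while
    flagging the division; it is an error only for direct callers.
    """


class MaskError(SCEDError):
    """A mask would leave fewer than two occasions in the statistic."""


class TestUndefinedError(SCEDError):
    """Every admissible division is degenerate; no test can be computed."""


class ConfigError(SCEDError):
    """Invalid run configuration (CLI/plot settings)."""
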