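"""Exception hierarchy.

Every error raised by this package derives from :class:`NCompareError` so
callers can catch one type at pipeline level while stages stay specific.
"""


class NCompareError(Exception):
    """Base class for all package errors."""


class FormatError(NCompareError):
    """A file does not have the expected layout (missing section, ragged rows)."""


class ParseError(NCompareError):
    """A field inside an otherwise well-formed file could not be parsed."""


class DuplicationError(NCompareError):
    """Duplicate probe names within a lane, or duplicate lane annotations."""


class AnnotationError(NCompareError):
    """A column header token could not be interpreted as a lane annotation."""


class DesignError(NCompareError):
    """An experiment design violates the balance invariants."""


class DesignMismatchError(NCompareError):
    """Observations handed to a model do not match the design it requires."""


class ConfigurationError(NCompareError):
    """Invalid or missing configuration (no control probes, bad enum value...)."""


class PairingError(NCompareError):
    """A lane expected in a concordance comparison is absent from the matrix."""


class UndefinedStatisticError(NCompareError):
    """A statistic is undefined on the given input (zero-variance correlation)."""
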