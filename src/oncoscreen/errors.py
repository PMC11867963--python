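"""Exception hierarchy.

All package errors derive from :class:`OncoscreenError` so callers (and the
CLI) can distinguish configuration problems from data problems.
"""


class OncoscreenError(Exception):
    """Base class for all oncoscreen errors."""


class ConfigurationError(OncoscreenError):
    """Invalid parameter, flag combination, or config file."""


class DataError(OncoscreenError):
    """Input data violates a precondition (empty stratum, no overlap, ...)."""


class FormatError(DataError):
    """A file does not follow the expected dialect."""


class ParseError(FormatError):
    """A cell or line could not be parsed; carries a location."""


class BarcodeError(FormatError):
    """A TCGA sample barcode is malformed."""


class NoValidCutoffError(DataError):
    """No expression threshold satisfies the cutoff-scan constraints."""


class UndefinedStatisticError(DataError):
    """A statistic is undefined for the given input (e.g. zero events)."""
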