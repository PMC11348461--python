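"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes: usage errors are handled by
click itself, :class:`FormatError`/:class:`ValidationError` signal bad
input data, and :class:`NumericalError` signals a well-formed problem the
numerics cannot solve (e.g. a rank-deficient design matrix).
"""


class GepqsarError(Exception):
    """Base class for all package-specific errors."""


class DomainError(GepqsarError, ValueError):
    """A value lies outside its scientific domain (e.g. inhibition > 100%)."""


class FormatError(GepqsarError, ValueError):
    """Malformed input file or table (duplicates, missing columns, bad cells)."""


class ValidationError(GepqsarError, ValueError):
    """An internal consistency invariant of a dataset or fixture failed."""


class ConfigError(GepqsarError, ValueError):
    """An invalid configuration value."""


class NumericalError(GepqsarError, ArithmeticError):
    """A numerically degenerate problem (singular design, perfect fit)."""
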