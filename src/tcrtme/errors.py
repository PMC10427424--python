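"""Exception hierarchy shared across the package."""


class TcrTmeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TcrTmeError):
    """Invalid generator or analysis configuration."""


class FormatError(TcrTmeError):
    """Malformed input file (missing columns, bad dtypes)."""


class DataError(TcrTmeError):
    """Values outside their valid domain (negative counts, percent > 100, ...)."""


class UsageError(TcrTmeError):
    """Operation called on inputs it is not defined for (mismatched patients, one group, ...)."""


class UndefinedValueError(TcrTmeError):
    """The requested statistic is undefined on this input (empty table, zero variance)."""


class EmptyModelError(TcrTmeError):
    """Penalised fit retained no predictors at the requested penalty."""


class ConsistencyError(TcrTmeError):
    """Cross-table bookkeeping violated (e.g. classification does not cover the key universe)."""
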