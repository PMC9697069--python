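"""Exception hierarchy shared across the package."""


class PipnError(Exception):
    """Base class for all package errors."""


class ValidationError(PipnError, ValueError):
    """Invalid input data or parameters."""


class EmptyStratumError(PipnError, ValueError):
    """A contingency table was requested on an empty report stratum."""


class UndefinedResultError(PipnError, ArithmeticError):
    """A statistic is undefined for the given counts (e.g. a zero cell
    without the Haldane–Anscombe correction)."""
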