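"""Exception hierarchy for hygrostab.

All domain/precondition violations raise :class:`DomainError` (a ValueError),
so callers can distinguish bad inputs from fit failures (:class:`FitError`).
"""


class HygrostabError(Exception):
    """Base class for all package errors."""


class DomainError(HygrostabError, ValueError):
    """An input violates a documented precondition or physical domain."""


class FitError(HygrostabError, RuntimeError):
    """A nonlinear fit failed to converge or the data are unidentifiable.

    Carries the diagnostics of the last attempt when available.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class FormatError(HygrostabError, ValueError):
    """An input file or image has the wrong structure (channels, columns)."""


class UnitError(HygrostabError, ValueError):
    """Incompatible or mixed time units within one series."""


class NeverReachedError(HygrostabError, ValueError):
    """A requested threshold is never attained by the model trajectory."""
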