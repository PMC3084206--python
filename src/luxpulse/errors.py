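"""Exception hierarchy used across the package.

All errors derive from :class:`LuxpulseError` so callers can catch the
package's failures with a single ``except`` clause; the subclasses keep the
distinction between bad configuration, bad data, and analyses that are
undefined for the given input.
"""


class LuxpulseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LuxpulseError):
    """A scenario, promoter, or parameter set violates its contract."""


class DomainError(LuxpulseError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class IntegrationError(LuxpulseError):
    """The ODE integrator produced a non-finite state.

    ``time`` records where along the trajectory the failure occurred.
    """

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class ParseError(LuxpulseError):
    """A plate-reader file failed validation; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class AnalysisError(LuxpulseError):
    """An analysis is undefined for the given series (e.g. no stationary phase)."""


class DataError(LuxpulseError):
    """Count data are internally inconsistent (e.g. positives > total)."""
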