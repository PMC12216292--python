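"""Exception hierarchy shared across the package.

``NanoswitchError`` covers everything raised intentionally; the CLI maps it
to exit code 1 (user error) while anything else becomes exit code 2.
"""


class NanoswitchError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(NanoswitchError, ValueError):
    """An input object violates a documented precondition."""


class ParseError(NanoswitchError, ValueError):
    """A file could not be parsed; the message names the offending line/field."""


class SingularInterfaceError(NanoswitchError, ZeroDivisionError):
    """Two adjacent media satisfy eps_upper + eps_lower == 0."""


class EmptySegmentationError(NanoswitchError, RuntimeError):
    """No pixel exceeded the segmentation threshold."""


class FitError(NanoswitchError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class AliasingError(NanoswitchError, ValueError):
    """A spectral component exceeds the Nyquist limit of the OPD sampling."""
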