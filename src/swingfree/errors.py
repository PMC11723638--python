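"""Exception types shared across the package."""


class SwingfreeError(Exception):
    """Base class for package errors."""


class IntegrationError(SwingfreeError):
    """Raised when a state becomes non-finite during integration.

    Attributes
    ----------
    time : float
        Simulation time at which the blow-up was detected.
    """

    def __init__(self, time: float, message: str | None = None):
        self.time = time
        super().__init__(message or f"integration blew up at t = {time:.6f} s")


class DegenerateModeError(SwingfreeError):
    """An eigenvalue pair is overdamped, repeated or non-oscillatory."""


class UntrimmableError(SwingfreeError):
    """A trial has no qualifying movement end (analogue of an excluded trial)."""


class ZeroVarianceError(SwingfreeError):
    """A statistic is undefined because the input has no variance."""


class FitFailureError(SwingfreeError):
    """Every candidate in a fit failed simulation or trimming."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class TrialParseError(SwingfreeError):
    """A trial file is malformed; message names the offending line/column."""
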