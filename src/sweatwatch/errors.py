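"""Exception hierarchy shared across the package."""


class SweatwatchError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SweatwatchError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class UnreachableTargetError(DomainError):
    """Requested temperature is at or above the steady-state asymptote."""


class InfeasibleDesignError(SweatwatchError):
    """No candidate fluid volume satisfies the design constraints."""


class CalibrationError(SweatwatchError, ValueError):
    """Calibration input is degenerate or a curve is unusable."""


class InsufficientDataError(SweatwatchError, ValueError):
    """Too few samples or records to compute the requested statistic."""


class DegenerateWindowError(InsufficientDataError):
    """Detection window has no time spread; a slope is undefined."""


class FormatError(SweatwatchError, ValueError):
    """A file does not conform to the expected layout."""


class TraceValidationError(SweatwatchError, ValueError):
    """A trace violates monotone/uniform-sampling requirements."""
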