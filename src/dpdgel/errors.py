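"""Exception hierarchy for dpdgel.

All errors raised by the library derive from :class:`DpdgelError`, so callers
(and the CLI) can distinguish configuration problems from runtime failures.
"""


class DpdgelError(Exception):
    """Base class for all dpdgel errors."""


class DomainError(DpdgelError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class RangeError(DpdgelError, ValueError):
    """A value lies outside the tabulated / supported range."""


class ParameterizationError(DpdgelError, ValueError):
    """A force-field parameterization produced an unphysical value."""


class TopologyError(DpdgelError, ValueError):
    """A network topology violates a structural invariant."""


class GeometryError(DpdgelError, ValueError):
    """A geometric construction cannot be satisfied (box too small, ...)."""


class BlowUpError(DpdgelError, RuntimeError):
    """The integrator became unstable (per-step displacement > box/2)."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"simulation blew up at step {step}")


class CoordinateError(DpdgelError, ValueError):
    """Wrapped coordinates were supplied where unwrapped ones are required."""


class InsufficientDataError(DpdgelError, ValueError):
    """A statistical estimator received too short a series."""


class ConfigError(DpdgelError, ValueError):
    """A run configuration file is malformed; carries the offending key path."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"config error at '{key}': {message}")


class TrajectoryParseError(DpdgelError, ValueError):
    """A trajectory file is malformed; carries the offending line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"trajectory parse error at line {line}: {message}")
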