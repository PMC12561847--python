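"""Exception hierarchy shared across the package."""


class HandicorError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(HandicorError, ValueError):
    """A generator or operation received an out-of-range parameter."""


class DegenerateMotionError(HandicorError):
    """Angular velocity vanished: the instantaneous center is at infinity."""


class FitError(HandicorError):
    """Curve fitting failed (rank deficiency, empty segment, underdetermined)."""


class AmbiguousMappingError(HandicorError):
    """Polar transform failed: the curve does not subtend a monotone angle."""


class DomainError(HandicorError):
    """An angle fell outside the curve's polar domain."""


class NumericalInconsistencyError(HandicorError):
    """Internal cross-check (e.g. law-of-cosines radius) disagreed."""


class EmptyInputError(HandicorError, ValueError):
    """An operation that needs at least one sample received none."""


class ConfigError(HandicorError, ValueError):
    """A topology / run configuration is invalid; message names the field."""


class SolverError(HandicorError):
    """Loop-closure Newton iteration failed to converge."""


class SingularConfigurationError(SolverError):
    """The closure Jacobian is singular at the current state."""


class UnsupportedJointError(HandicorError, ValueError):
    """A crossing-type pair was requested at a joint that does not take one."""


class DimensionError(HandicorError, ValueError):
    """Mixed 2-D / 3-D trajectory inputs."""


class UndefinedBaselineError(HandicorError, ZeroDivisionError):
    """Percent reduction against a zero baseline."""


class DegenerateTestError(HandicorError):
    """Paired test with zero-variance differences."""


class ParseError(HandicorError, ValueError):
    """A CSV/JSON input violated its schema; message carries the location."""
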