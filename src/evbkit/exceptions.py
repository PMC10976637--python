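"""Exception hierarchy for evbkit."""


class EVBError(Exception):
    """Base class for all evbkit errors."""


class InvalidInputError(EVBError, ValueError):
    """Raised for non-finite, malformed, or out-of-range inputs."""


class DegenerateStateError(EVBError):
    """Raised when the ground-state eigenvector is undefined (h12 = 0 and u1 = u2)."""


class MonotoneProfileError(EVBError):
    """Raised when a free-energy profile has no interior maximum between two minima."""


class ProfileCoverageError(EVBError):
    """Raised when the sampled windows leave a hole in the reaction-coordinate histogram."""


class CalibrationError(EVBError):
    """Raised when (h12, delta_alpha) calibration fails to reach the target tolerance."""


class TrajectoryParseError(EVBError):
    """Raised for malformed trajectory tables, naming the offending file and line."""
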