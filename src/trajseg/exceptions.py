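"""Exception hierarchy shared across the package."""


class TrajsegError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TrajsegError):
    """A configuration value (column map, window spec, model config) is invalid."""


class TrajectoryParseError(TrajsegError):
    """A trajectory file could not be parsed; carries the offending row."""


class ValidationError(TrajsegError):
    """Data violates an invariant (duplicate frames, missing labels, ...)."""


class TrainingError(TrajsegError):
    """Optimization failed (e.g. non-finite loss)."""
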