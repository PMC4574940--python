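"""Exception hierarchy.

Every error raised by the library derives from :class:`MeegError` so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class MeegError(Exception):
    """Base class for all meegconnet errors."""


class FormatError(MeegError):
    """A file could not be parsed as the expected on-disk dialect."""


class ValidationError(MeegError):
    """An in-memory object violates a domain invariant (NaNs, duplicate
    labels, asymmetric adjacency, ...)."""


class ParameterError(MeegError, ValueError):
    """A user-supplied parameter is outside its admissible range."""


class StateError(MeegError):
    """An operation was called before its prerequisite state was set
    (e.g. noise covariance without a baseline span)."""


class AlignmentError(MeegError):
    """Labels/rows of two artifacts that must correspond do not."""


class EstimatorError(MeegError):
    """The requested estimator is not applicable to the data at hand."""


class ShapeError(MeegError):
    """An array does not have the required dimensionality or shape."""


class ConfigError(MeegError):
    """A pipeline configuration is invalid (bad stage chain, missing file)."""
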