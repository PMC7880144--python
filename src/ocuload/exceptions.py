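"""Exception hierarchy shared across the package."""


class OculoadError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OculoadError):
    """A parameter, dialect or config file is invalid."""


class ValidationError(OculoadError):
    """Input data violates a structural precondition."""


class InsufficientDataError(OculoadError):
    """Too few (valid) samples to compute the requested quantity."""


class EmptyInputError(OculoadError):
    """A file or stream contained no usable rows."""


class DivergenceError(OculoadError):
    """A simulated control loop diverged (unstable gain configuration)."""


class UndefinedCorrelationError(OculoadError):
    """Correlation requested on a zero-variance input."""
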