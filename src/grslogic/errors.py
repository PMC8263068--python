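"""Exception types shared across the package."""


class GrsLogicError(Exception):
    """Base class for all grslogic errors."""


class InvalidInputError(GrsLogicError, ValueError):
    """Raised when numeric inputs are out of range or non-finite."""


class InvalidParameterError(GrsLogicError, ValueError):
    """Raised when model parameters violate their invariants."""


class ConfigurationError(GrsLogicError, ValueError):
    """Raised for unknown names, bad ranges, or malformed run configuration."""


class DegenerateInputError(GrsLogicError, ValueError):
    """Raised when an input is structurally valid but degenerate (e.g. all zeros)."""


class InsufficientDataError(GrsLogicError, ValueError):
    """Raised when an estimator receives too few observations."""


class SchemaError(GrsLogicError, ValueError):
    """Raised when a tabular input does not match the expected schema."""


class EstimationFailureError(GrsLogicError, RuntimeError):
    """Raised when every optimizer restart fails to converge."""
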