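"""Exception hierarchy shared across the package."""


class CytopointError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CytopointError):
    """An input table or file is missing required structure."""


class ValidationError(CytopointError):
    """Input data violates a documented invariant."""


class ConfigError(CytopointError):
    """A configuration value is out of its admissible range."""


class PreconditionError(CytopointError):
    """An operation was called with inputs that violate its contract."""
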