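"""Exception types shared across the package."""


class GCMMError(Exception):
    """Base class for all package errors."""


class SchemaError(GCMMError):
    """Raised when an input table does not match the bound catalog/schema."""


class ConfigError(GCMMError):
    """Raised for invalid configuration or generator parameters."""


class FitError(GCMMError):
    """Raised when a statistical fit cannot be computed (degenerate design,
    single-class outcome, non-convergence, excessive bootstrap failures)."""
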