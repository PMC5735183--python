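"""Exception types shared across the package."""


class OculostimError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(OculostimError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(OculostimError, ValueError):
    """A simulation or analysis configuration is inconsistent or incomplete."""


class SchemaError(OculostimError, ValueError):
    """An input table is missing required columns or has malformed values."""


class DegenerateInputError(OculostimError, ValueError):
    """Input data are too degenerate for the requested computation
    (e.g. singular covariance, fewer points than required)."""


class UnsupportedDesignError(OculostimError, ValueError):
    """A factorial design cannot be analyzed (e.g. empty cells with an
    interaction term)."""
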