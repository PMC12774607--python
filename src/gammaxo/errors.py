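"""Exception types shared across the package."""


class GammaxoError(Exception):
    """Base class for all package-specific errors."""


class DataValidationError(GammaxoError):
    """Raised when input data violate the documented invariants.

    The message names the offending record so users can locate it in the
    source table.
    """


class SeriesConvergenceError(GammaxoError):
    """Raised when the thinning series hits its term cap before reaching
    the requested relative tolerance."""


class ConfigError(GammaxoError):
    """Raised for invalid pipeline configuration."""
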