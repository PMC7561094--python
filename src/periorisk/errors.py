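"""Exception types shared across the package."""


class PerioriskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PerioriskError, ValueError):
    """A generator or study configuration violates its invariants."""


class SpecificationError(PerioriskError, ValueError):
    """A risk-model specification cannot be resolved against a record."""


class SpecLoadError(PerioriskError, ValueError):
    """A risk-model specification file failed schema validation."""


class DomainError(PerioriskError, ValueError):
    """An argument lies outside the mathematically valid domain."""


class FitError(PerioriskError, RuntimeError):
    """Maximum-likelihood estimation failed (separation, empty level,
    non-convergence)."""
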