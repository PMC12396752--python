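"""Exception types shared across the package."""


class OcotilloError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OcotilloError, ValueError):
    """A numeric parameter violates its contract (e.g. train <= 0, k too large)."""


class InvalidMaskError(OcotilloError, ValueError):
    """A bit mask is empty or malformed where a non-empty mask is required."""


class InvalidSpecError(OcotilloError, ValueError):
    """A generator or search-space specification violates its invariants."""


class ConfigError(OcotilloError, ValueError):
    """A run configuration failed to parse or validate."""


class NotFoundError(OcotilloError, LookupError):
    """A search (e.g. confusion-matrix reconstruction) found no admissible solution."""


class UndefinedTestError(OcotilloError, ValueError):
    """A statistical test is undefined for the given input (e.g. all-zero differences)."""
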