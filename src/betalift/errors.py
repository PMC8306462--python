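"""Exception hierarchy.

All errors raised intentionally by this package derive from
:class:`BetaliftError`, so callers (notably the CLI) can distinguish
user-facing problems from genuine bugs.
"""


class BetaliftError(Exception):
    """Base class for all betalift errors."""


class ConfigError(BetaliftError):
    """A configuration value is missing, malformed, or out of range."""


class SchemaError(BetaliftError):
    """A required column is absent from an input table."""


class ValidationError(BetaliftError):
    """Input rows or values violate a contract (e.g. non-binary outcome)."""


class DataError(BetaliftError):
    """The data are structurally valid but unusable for the requested
    computation (zero cells, empty arms, degenerate tables)."""


class SeparationError(DataError):
    """Complete separation in a logistic fit; names the offending level."""
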