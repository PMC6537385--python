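"""Exception hierarchy.

All package errors derive from :class:`PhenosomError` so callers (notably the
CLI) can distinguish bad input (exit code 1) from internal faults (exit 2).
"""


class PhenosomError(Exception):
    """Base class for all package errors."""


class ConfigError(PhenosomError, ValueError):
    """A configuration object violates its invariants; names the field."""


class InputError(PhenosomError, ValueError):
    """Malformed data passed to an operation."""


class SchemaError(InputError):
    """Data does not conform to the declared phenotype schema."""


class DegenerateError(PhenosomError, ValueError):
    """An operation hit a degenerate case (zero variance, rank-0 input...)."""


class NotApplicableError(PhenosomError, ValueError):
    """A statistic is undefined for the given partition (e.g. k = 1)."""
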