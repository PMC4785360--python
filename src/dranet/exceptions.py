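"""Exception hierarchy for dranet.

All errors raised by the package derive from :class:`DranetError` so callers
can catch package failures with a single except clause.
"""


class DranetError(Exception):
    """Base class for all dranet errors."""


class FormatError(DranetError, ValueError):
    """A file violates its format contract (duplicate ids, bad field counts...)."""


class ParseError(DranetError, ValueError):
    """A cell or token could not be parsed; the message names the location."""


class SchemaError(DranetError, ValueError):
    """A table is missing required columns."""


class ValidationError(DranetError, ValueError):
    """Parsed values violate a domain invariant (negative age, p outside [0,1])."""


class InputError(DranetError, ValueError):
    """Analysis inputs are incompatible (no overlapping samples, empty query...)."""


class ConfigError(DranetError, ValueError):
    """A configuration value is out of its allowed range."""


class DegenerateInputError(DranetError, ValueError):
    """Input is too degenerate for the statistic (zero variance, group too small)."""
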