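"""Exception hierarchy.

``InputError`` covers anything attributable to user-supplied data or
configuration (CLI exit code 1); everything else is an internal error
(exit code 2).
"""


class RipseekError(Exception):
    """Base class for all package errors."""


class InputError(RipseekError):
    """Invalid user input: malformed sequence, table, or parameter."""


class ConfigError(InputError):
    """A configuration object violates its invariants."""


class GenerationError(RipseekError):
    """Synthetic-data generation could not satisfy its constraints."""
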