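"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage/config errors -> 2,
data validation errors -> 3, numerical failures -> 4.
"""


class SphingostateError(Exception):
    """Base class for all package errors."""


class ConfigError(SphingostateError):
    """Invalid configuration or usage (CLI exit code 2)."""


class ParseError(SphingostateError):
    """A file could not be parsed (CLI exit code 3)."""


class ValidationError(SphingostateError):
    """Parsed data violates an invariant (CLI exit code 3)."""


class SchemaError(ValidationError):
    """A table is missing required columns or pairing structure."""


class ContractError(SphingostateError):
    """A user-supplied callable violated its contract (CLI exit code 4)."""


class NumericalError(SphingostateError):
    """A computation is undefined on the given input (CLI exit code 4)."""
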