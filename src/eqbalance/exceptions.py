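"""Exception hierarchy.

Exit-code mapping used by the CLI: I/O errors -> 2, schema/config errors -> 3,
numerical failures -> 4.
"""


class EqBalanceError(Exception):
    """Base class for all package errors."""


class DimensionError(EqBalanceError, ValueError):
    """Array shapes or lengths are inconsistent."""


class ConfigurationError(EqBalanceError, ValueError):
    """An invalid parameter or run configuration."""


class SchemaError(EqBalanceError, ValueError):
    """A file or field layout does not match the expected schema."""


class EmptyInputError(EqBalanceError, ValueError):
    """An operation received no usable (masked-in) data."""


class InsufficientDataError(EqBalanceError, ValueError):
    """Too few points for the requested fit."""


class IntegrationError(EqBalanceError, RuntimeError):
    """A bundled simulation diverged or failed."""


class SizeError(EqBalanceError, ValueError):
    """Problem size exceeds a hard combinatorial limit."""
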