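"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: validation errors -> 2,
insufficient data -> 3.
"""


class PBMAError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PBMAError):
    """An input violates a structural or range constraint."""

    exit_code = 2


class InsufficientDataError(PBMAError):
    """A computation has no data to operate on (empty panel, no regions...)."""

    exit_code = 3


class ConfigurationError(ValidationError):
    """A configuration object is internally inconsistent."""


class SizeError(PBMAError):
    """A problem instance is too large for the exhaustive algorithm."""

    exit_code = 2
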