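"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: validation/contract errors -> 2,
file-format/schema errors -> 3, degenerate inputs -> 4.
"""


class ScrelmapError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigError(ScrelmapError):
    """Invalid configuration or missing input path."""

    exit_code = 2


class ContractError(ScrelmapError):
    """A call violated an operation's precondition."""

    exit_code = 2


class FormatError(ScrelmapError):
    """A file could not be parsed as the expected format."""

    exit_code = 3


class SchemaError(FormatError):
    """A parsed table lacks required columns or rows."""

    exit_code = 3


class DegenerateInputError(ScrelmapError):
    """Input is structurally valid but statistically unusable."""

    exit_code = 4
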