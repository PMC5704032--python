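"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the command-line interface:
config error -> 2, parse error -> 3, contract violation -> 4.
"""


class TwinQuadError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(TwinQuadError):
    """Invalid configuration value (negative threshold, missing path, ...)."""

    exit_code = 2


class ParseError(TwinQuadError):
    """Malformed input file; message carries file and record position."""

    exit_code = 3


class ContractViolation(TwinQuadError):
    """A stage was called outside its precondition (e.g. parental

    classification requested in twin-only mode)."""

    exit_code = 4
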