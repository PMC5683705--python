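"""Exception hierarchy shared across the pipeline.

CLI exit codes: ConfigError -> 2, DataError (incl. ParseError) -> 3.
"""


class NetmodError(Exception):
    """Base class for all package errors."""


class ConfigError(NetmodError):
    """Invalid parameter, threshold, or pipeline configuration."""


class DataError(NetmodError):
    """Input data violates a documented precondition or invariant."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line/cell."""
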