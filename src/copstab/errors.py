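"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems exit 3.
"""


class CopstabError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(CopstabError):
    """Invalid configuration or parameter value (CLI exit code 2)."""


class FormatError(CopstabError):
    """A file does not conform to the documented on-disk format (exit 3)."""


class DataError(CopstabError):
    """Well-formed input whose content violates an invariant (exit 3)."""
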