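"""Exception hierarchy shared across the package.

``ConfigError`` marks a problem with user-supplied parameters or file
layout (CLI exit code 2); ``DataError`` marks inputs that parse but
violate the domain invariants (CLI exit code 3).
"""


class ClineSeasError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ClineSeasError):
    """Invalid configuration: missing column, bad parameter, absent input."""


class DataError(ClineSeasError):
    """Input rows or values that violate a documented invariant."""
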