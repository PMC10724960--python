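"""Exception hierarchy shared across the package.

``ConfigError`` and ``ValidationError`` map to CLI exit code 2,
everything else to 1.
"""


class CSSMOError(Exception):
    """Base class for all package errors."""


class ConfigError(CSSMOError, ValueError):
    """Invalid configuration value or infeasible specification."""


class ValidationError(CSSMOError, ValueError):
    """Data violates a documented invariant or precondition."""


class FormatError(CSSMOError, ValueError):
    """Input file does not match the expected delimited layout."""
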