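"""Exceptions shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class ConfigError(ValueError):
    """Invalid configuration (bad parameter value, inconsistent options)."""


class DataError(ValueError):
    """Invalid or degenerate input data (shape mismatch, constant series, ...)."""
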