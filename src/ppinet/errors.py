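"""Exception hierarchy shared across the package.

The CLI maps :class:`ConfigError` to exit code 2 and :class:`DataError`
to exit code 3.
"""


class PPINetError(Exception):
    """Base class for all package errors."""


class ConfigError(PPINetError):
    """Invalid configuration (bad threshold, unknown key, missing input)."""


class DataError(PPINetError):
    """Malformed or inconsistent input data."""
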