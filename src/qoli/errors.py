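"""Exception hierarchy shared across the package."""


class QoliError(Exception):
    """Base class for all package errors."""


class ValidationError(QoliError, ValueError):
    """Invalid input data (out-of-range value, malformed row, bad trajectory)."""


class ConfigError(QoliError, ValueError):
    """Invalid run configuration."""
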