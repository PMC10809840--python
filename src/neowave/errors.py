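"""Exception hierarchy shared across the pipeline."""


class NeowaveError(Exception):
    """Base class for all neowave errors."""


class ConfigError(NeowaveError):
    """Invalid configuration value or file (CLI exit code 2)."""


class DataError(NeowaveError):
    """Unreadable, malformed, or inconsistent input data (CLI exit code 3)."""
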