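"""Exception hierarchy shared across the package."""


class TaskcrnnError(Exception):
    """Base class for all taskcrnn errors."""


class ShapeError(TaskcrnnError, ValueError):
    """An array did not have the shape an operation requires."""


class ConfigError(TaskcrnnError, ValueError):
    """A configuration value or file is invalid."""


class DataError(TaskcrnnError, ValueError):
    """Input data is malformed or inconsistent with its metadata."""
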