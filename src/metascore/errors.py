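"""Exception hierarchy used across the package."""


class MetascoreError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MetascoreError, ValueError):
    """Invalid configuration value or impossible parameter combination."""


class FormatError(MetascoreError, ValueError):
    """Malformed input file (dimension/id mismatch, bad syntax)."""


class DataError(MetascoreError, ValueError):
    """Well-formed file with invalid data (negative counts, NaN, ...)."""


class EmptyDataError(MetascoreError, ValueError):
    """An operation removed or received every cell/gene."""
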