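"""Exception hierarchy.

Config problems and data problems are distinct so the CLI can map them to
distinct exit codes (2 and 3 respectively).
"""


class CalanFeedError(Exception):
    """Base class for all package errors."""


class ConfigError(CalanFeedError):
    """Invalid configuration value or combination."""


class FormatError(CalanFeedError):
    """Input file does not match the expected layout (e.g. missing column)."""


class DataError(CalanFeedError):
    """Input parsed but the values violate a contract (units, monotone time...)."""


class InsufficientDataError(DataError):
    """Too few records survive filtering for the requested fit to be stable."""


class FitError(CalanFeedError):
    """Mixture estimation failed (all restarts degenerate)."""
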