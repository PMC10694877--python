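"""Exception hierarchy shared across the pipeline."""


class AADSignalError(Exception):
    """Base class for all package errors."""


class FormatError(AADSignalError):
    """A table file violates the expected layout (missing column, ragged row)."""


class InvalidDateError(AADSignalError):
    """A date string is non-numeric or names an impossible calendar date."""


class ConfigurationError(AADSignalError):
    """A configuration value or file is invalid or inconsistent."""


class NoDataError(AADSignalError):
    """An operation that needs at least one record received none."""
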