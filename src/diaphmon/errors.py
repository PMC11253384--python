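"""Exception hierarchy shared across the package."""


class DiaphmonError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DiaphmonError, ValueError):
    """A parameter violates its documented precondition."""


class FormatError(DiaphmonError, ValueError):
    """A waveform or table file violates the declared text format."""


class MissingChannelError(DiaphmonError, KeyError):
    """An operation requires a channel the record does not carry."""


class SynchronizationError(DiaphmonError, ValueError):
    """Sync channels cannot be aligned (flat signal or no overlap)."""


class InsufficientDataError(DiaphmonError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(DiaphmonError, ValueError):
    """Input is degenerate for the requested computation (e.g. all x equal)."""


class ConfigError(DiaphmonError, ValueError):
    """A study configuration file is invalid."""
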