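"""Exception hierarchy shared across the package.

The CLI maps :class:`ValidationError` subclasses to exit code 2 and
:class:`DataError` subclasses to exit code 3.
"""


class SpikeCollideError(Exception):
    """Base class for all package errors."""


class ValidationError(SpikeCollideError, ValueError):
    """Invalid parameter or configuration value."""


class ParameterError(ValidationError):
    """A numeric argument is out of its valid range."""


class ConfigError(ValidationError):
    """A configuration file contains an unknown or out-of-range key."""


class ShapeError(ValidationError):
    """An array argument has the wrong shape (e.g. not 4 tetrode channels)."""


class SchedulingError(ValidationError):
    """A stimulation schedule cannot be fit into the session."""


class DataError(SpikeCollideError):
    """Problems with on-disk data files."""


class MetadataError(DataError):
    """Sidecar metadata is missing, malformed, or inconsistent."""


class TruncatedFileError(DataError):
    """Binary payload size does not match the advertised layout."""


class ChannelMismatchError(DataError):
    """Channel count in the payload disagrees with the metadata."""


class DivisionGuardError(SpikeCollideError, ZeroDivisionError):
    """A noise or normalization denominator was exactly zero."""
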