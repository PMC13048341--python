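"""Exception hierarchy shared across svdkit modules.

All errors derive from :class:`SvdKitError` so callers (and the CLI) can
catch package failures with one except clause. Subclasses also derive from
``ValueError`` so plain scientific scripting code behaves as expected.
"""


class SvdKitError(Exception):
    """Base class for all svdkit errors."""


class BackendNotFoundError(SvdKitError, KeyError):
    """Requested numeric backend is not registered."""


class DeviceUnavailableError(SvdKitError, RuntimeError):
    """Requested device (e.g. GPU) is not available on this backend."""


class MatrixParseError(SvdKitError, ValueError):
    """Input matrix file could not be parsed."""


class DimensionMismatchError(SvdKitError, ValueError):
    """Declared dimensions or name counts do not match the data."""


class InvalidValueError(SvdKitError, ValueError):
    """Matrix contains a value the operation cannot accept (NaN, negative under log, ...)."""


class OrientationError(SvdKitError, ValueError):
    """Matrix orientation cannot be determined automatically."""


class RankError(SvdKitError, ValueError):
    """Requested rank/truncation is invalid for the decomposition at hand."""


class MetricError(SvdKitError, ValueError):
    """A validation metric is undefined for the given inputs."""


class ConfigError(SvdKitError, ValueError):
    """Pipeline configuration failed validation."""
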