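"""Exception hierarchy shared across the package."""


class KarstSegError(Exception):
    """Base class for all package errors."""


class FormatError(KarstSegError):
    """A file exists but is not in an accepted raster format."""


class DataError(KarstSegError):
    """Input data violates a contract (shape mismatch, all-nodata, ...)."""


class LegendMismatchError(DataError):
    """A label raster contains colors or values absent from the legend."""

    def __init__(self, offenders, message=None):
        self.offenders = list(offenders)
        super().__init__(
            message or f"values/colors not present in legend: {self.offenders}"
        )


class ConfigError(KarstSegError):
    """An invalid configuration (architecture, tile scheme, recipe, ...)."""


class UsageError(KarstSegError, ValueError):
    """An API was called with arguments outside its domain."""
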