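"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`RoiFinderError` so callers can
distinguish pipeline failures from programming errors.
"""


class RoiFinderError(Exception):
    """Base class for all pipeline errors."""


class ChannelNotFoundError(RoiFinderError, KeyError):
    """A requested element channel is not present in the scan."""

    def __init__(self, channel: str, available=None):
        self.channel = channel
        self.available = list(available) if available is not None else None
        msg = f"channel {channel!r} not found"
        if self.available is not None:
            msg += f" (available: {', '.join(self.available)})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg otherwise
        return self.args[0]


class FormatError(RoiFinderError):
    """A file or in-memory object violates the documented layout."""


class DegenerateImageError(RoiFinderError):
    """Image has too little contrast to threshold (e.g. constant)."""


class PlacementError(RoiFinderError):
    """Synthetic cells could not be placed without overlap."""


class ConfigError(RoiFinderError):
    """Invalid configuration value."""


class ZeroVarianceError(RoiFinderError):
    """A feature column is constant and cannot be standardized."""

    def __init__(self, feature: str):
        self.feature = feature
        super().__init__(f"feature {feature!r} has zero variance")
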