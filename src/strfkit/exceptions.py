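"""Exception hierarchy shared across the package."""


class StrfkitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StrfkitError, ValueError):
    """A parameter violates its documented domain."""


class NoSpikesError(StrfkitError):
    """An STA was requested for a spike train with no usable spikes."""


class DegenerateFitError(StrfkitError):
    """A null-distribution fit was attempted on a degenerate sample."""


class TooFewClustersError(StrfkitError):
    """Not enough null cluster masses to fit a gamma distribution.

    Carries the gain level at which the shortage occurred so callers can
    mark that grid cell unavailable.
    """

    def __init__(self, message: str, gain_level: float | None = None):
        super().__init__(message)
        self.gain_level = gain_level


class UnavailableSettingError(StrfkitError):
    """A correction setting refers to a (gain, cluster) grid cell with no fit."""


class NoValidSettingError(StrfkitError):
    """Threshold selection found no setting with a defined accuracy."""
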