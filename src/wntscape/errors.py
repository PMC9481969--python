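"""Exception hierarchy.

Every error raised by the package derives from :class:`WntscapeError` so
callers can catch the package's failures with a single except clause.
"""


class WntscapeError(Exception):
    """Base class for all wntscape errors."""


class GridCompatibilityError(WntscapeError):
    """Two volumes do not share shape and voxel size."""


class ValidationError(WntscapeError):
    """A catalogue, manifest or configuration violates an invariant."""


class EmptySelectionError(WntscapeError):
    """A family/stage filter matched no domains."""


class ThresholdError(WntscapeError):
    """An occupancy threshold exceeds the number of summed domains."""


class ParameterError(WntscapeError):
    """An operation parameter is out of its legal range."""


class PlacementError(WntscapeError):
    """The phantom generator could not place the requested geometry."""


class ConfigurationError(WntscapeError):
    """A grid or phantom configuration is unusable."""


class UndefinedStatisticError(WntscapeError):
    """A statistic is undefined for the given input (e.g. empty domain)."""
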