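"""Exception hierarchy.

Every error raised by this package derives from :class:`VoxcorrError`, so
callers (and the CLI) can distinguish package errors from programming bugs.
"""


class VoxcorrError(Exception):
    """Base class for all voxcorr errors."""


class DimensionError(VoxcorrError):
    """Missing or contradictory hyperstack dimension metadata."""


class LayoutError(VoxcorrError):
    """TIFF page count inconsistent with declared C*Z*T layout."""


class AddressError(VoxcorrError, IndexError):
    """Plane or voxel address outside the hyperstack bounds."""


class RangeError(VoxcorrError):
    """Empty or out-of-bounds crop interval."""


class WriteError(VoxcorrError, IOError):
    """Failure while writing an output file."""


class ParameterError(VoxcorrError, ValueError):
    """Invalid parameter value (negative sigma, even window, ...)."""


class NoFramesError(VoxcorrError):
    """No frame scans detectable in a galvanometer trace."""


class PreAcquisitionError(VoxcorrError):
    """Sample time precedes the first detected imaging frame."""


class RoiError(VoxcorrError):
    """Empty, out-of-bounds, or otherwise invalid ROI."""


class DegenerateTraceError(VoxcorrError):
    """Operation undefined on a constant trace (e.g. min/max normalization)."""


class ParseError(VoxcorrError, ValueError):
    """Malformed external trace / config / table file."""


class TimeError(VoxcorrError):
    """Non-monotonic or otherwise unusable time column."""


class CoverageError(VoxcorrError):
    """External trace does not cover the acquisition interval."""


class LagError(VoxcorrError):
    """Lag leaves less than the minimum overlap between trace and stimulus."""


class ShapeError(VoxcorrError):
    """Array shape mismatch between stack, stimulus, or mask."""


class MaskError(VoxcorrError):
    """Empty or mismatched analysis mask."""


class DurationError(VoxcorrError):
    """Protocol or recording duration too short."""


class TruthError(VoxcorrError):
    """Empty or inconsistent ground-truth specification."""
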