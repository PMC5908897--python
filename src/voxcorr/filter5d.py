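"""Separable Gaussian smoothing of 5D stacks plus DC-offset noise blanking.

Smoothing acts on up to four axes (x, y, z, t) but never across channels:
each channel is filtered independently.  The filter is implemented as a
sequence of 1D Gaussian convolutions (one per axis with sigma > 0) with
kernels truncated at radius ``ceil(4 * sigma)`` and renormalized to unit
sum, so constants are preserved exactly up to float rounding.

The DC-offset step zeroes every voxel strictly below a threshold.  It is a
noise-floor blanking (useful against low-level electrical pickup), not a
baseline subtraction, and when combined with smoothing it is applied
*before* the Gaussian — blanking afterwards would re-introduce
sub-threshold values at transient edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .hyperstack import Hyperstack

__all__ = ["FilterParams", "dc_blank", "gaussian_filter_5d", "BOUNDARY_MODES"]

#: boundary modes exposed to callers -> scipy.ndimage mode names.
#: "mirror" reflects about the edge voxel without duplicating it
#: (constant-preserving); "reflect" duplicates the edge voxel.
BOUNDARY_MODES = {
    "mirror": "mirror",
    "reflect": "reflect",
    "nearest": "nearest",
    "wrap": "wrap",
    "constant": "constant",
}


@dataclass(frozen=True)
class FilterParams:
    """Per-axis Gaussian sigmas (voxels/frames), DC offset, boundary mode."""

    sigma_x: float = 0.0
    sigma_y: float = 0.0
    sigma_z: float = 0.0
    sigma_t: float = 0.0
    dc_offset: float = 0.0
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        for name in ("sigma_x", "sigma_y", "sigma_z", "sigma_t"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0; got {v}")
        if not math.isfinite(self.dc_offset) or self.dc_offset < 0:
            raise ParameterError(f"dc_offset must be finite and >= 0; got {self.dc_offset}")
        if self.boundary not in BOUNDARY_MODES:
            raise ParameterError(
                f"boundary must be one of {sorted(BOUNDARY_MODES)}; got {self.boundary!r}"
            )


def dc_blank(stack: Hyperstack, threshold: float) -> Hyperstack:
    """Zero every voxel with value strictly below ``threshold``."""
    if not math.isfinite(threshold) or threshold < 0:
        raise ParameterError(f"threshold must be finite and >= 0; got {threshold}")
    data = stack.data.copy()
    data[data < threshold] = 0
    return stack.with_data(data)


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Truncated (radius ceil(4*sigma)), unit-sum 1D Gaussian kernel."""
    radius = math.ceil(4.0 * sigma)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_filter_5d(stack: Hyperstack, params: FilterParams) -> Hyperstack:
    """Gaussian-smooth a hyperstack along x, y, z and/or t.

    Axes with sigma 0 are skipped; the channel axis is never filtered.
    If ``params.dc_offset`` > 0, sub-threshold voxels are blanked first.
    Output dtype is always float32.
    """
    if params.dc_offset > 0:
        stack = dc_blank(stack, params.dc_offset)
    data = stack.data.astype(np.float32, copy=True)
    mode = BOUNDARY_MODES[params.boundary]
    # canonical data axes: (c=0, t=1, z=2, y=3, x=4)
    for axis, sigma in ((1, params.sigma_t), (2, params.sigma_z),
                        (3, params.sigma_y), (4, params.sigma_x)):
        if sigma > 0:
            radius = math.ceil(4.0 * sigma)
            data = ndimage.gaussian_filter1d(
                data, sigma=sigma, axis=axis, mode=mode,
                truncate=radius / sigma, output=np.float32,
            )
    return stack.with_data(data)
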