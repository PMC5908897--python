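"""Voxel-wise normalized cumulative cross-correlation against a stimulus.

The detector screens a 5D Ca2+ stack for stimulus-locked responses.  For
every voxel the fluorescence trace F(t) is (optionally) pre-averaged over
an in-plane (2m+1)^2 neighborhood, normalized (running-percentile dF/F0 by
default), and correlated against a per-stack stimulus vector s(t) at lags
k = 0..K, where positive lag means the fluorescence *follows* the
stimulus:

    r_k = Pearson( s[0 : T-k],  F[k : T] )

Two per-voxel statistics are available:

* ``cumulative``:  R = sum_{k=0}^{K} r_k  (area under the lag curve) —
  tolerant to trial-to-trial jitter in the response delay, because a
  response landing anywhere inside the lag window contributes;
* ``peak``:        R = max_k r_k (with the argmax lag, ties to the
  smallest lag) — the classical choice, sharper but jitter-sensitive.

Significance is calibrated with a circular-shift null: the stimulus vector
is rotated by random offsets (preserving its autocorrelation), the
statistic recomputed on a voxel subsample, and the pooled null percentile
(default 99.9) becomes the detection threshold.  The fraction of
suprathreshold voxels is the "responding volume".

Degenerate (zero-variance) overlaps never raise: they contribute r = 0 so
maps stay finite everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import LagError, MaskError, ParameterError, ShapeError
from .hyperstack import Hyperstack
from .sync import StimVector

__all__ = [
    "CorrelationParams",
    "CorrelationMap",
    "NullResult",
    "normalize_trace",
    "pearson_at_lag",
    "cumulative_xcorr",
    "peak_xcorr",
    "xy_boxmean",
    "correlation_map",
    "shift_null",
    "responding_volume",
    "MIN_OVERLAP",
]

#: minimum number of overlapping samples for a per-lag Pearson coefficient
MIN_OVERLAP = 8

_NORM_METHODS = ("dff_running_percentile", "zscore", "none")


@dataclass(frozen=True)
class CorrelationParams:
    """Detector parameters.

    lag_window_frames
        K, the largest lag summed/searched; typical choices correspond to
        2.5 or 5 s of acquisition (K = round(seconds / stack_period_s)).
    xy_halfwidth
        m, in-plane pre-averaging radius; 0 disables.
    mode
        ``cumulative`` or ``peak``.
    normalization / norm_window_frames
        Per-voxel trace normalization; for the running-percentile dF/F0
        the window half-width defaults to the lag window (None -> K, i.e.
        F0 at frame i is the 10th percentile of frames [i-K, i+K]).
    n_null / null_percentile / null_subsample / seed
        Circular-shift null configuration.
    """

    lag_window_frames: int = 10
    xy_halfwidth: int = 0
    mode: str = "cumulative"
    normalization: str = "dff_running_percentile"
    norm_window_frames: int | None = None
    n_null: int = 200
    null_percentile: float = 99.9
    null_subsample: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag_window_frames < 0:
            raise ParameterError("lag_window_frames must be >= 0")
        if self.xy_halfwidth < 0:
            raise ParameterError("xy_halfwidth must be >= 0")
        if self.mode not in ("cumulative", "peak"):
            raise ParameterError(f"mode must be cumulative|peak; got {self.mode!r}")
        if self.normalization not in _NORM_METHODS:
            raise ParameterError(
                f"normalization must be one of {_NORM_METHODS}; got {self.normalization!r}"
            )
        if self.n_null < 0:
            raise ParameterError("n_null must be >= 0")
        if not 0 < self.null_percentile < 100:
            raise ParameterError("null_percentile must be in (0, 100)")

    @property
    def norm_window(self) -> int:
        return (
            self.lag_window_frames
            if self.norm_window_frames is None
            else self.norm_window_frames
        )


@dataclass
class CorrelationMap:
    """Per-voxel statistic over (z, y, x) for one channel, plus context."""

    values: np.ndarray
    params: CorrelationParams
    mask: np.ndarray | None = None
    null_threshold: float | None = None
    p_values: np.ndarray | None = None
    lag_at_peak: np.ndarray | None = None
    degenerate: bool = False


class NormalizedTrace(NamedTuple):
    values: np.ndarray
    degenerate: bool


# ---------------------------------------------------------------------------
# trace normalization
# ---------------------------------------------------------------------------

def _running_percentile(block: np.ndarray, window: int, q: float = 10.0) -> np.ndarray:
    """Centered running percentile along axis 0 with edge-shrunk windows.

    ``block`` is (T,) or (T, N); ``window`` is the *half-width*: the
    window at index i spans [i - window, i + window], clipped at the
    trace ends.  With window = K the F0 estimate at any frame draws on
    one full correlation window on each side, so a stimulus-locked
    transient (which occupies at most ~K frames) cannot dominate the low
    percentile and inflate its own baseline.
    """
    T = block.shape[0]
    h = max(window, 1)
    out = np.empty_like(block, dtype=np.float64)
    for i in range(T):
        lo = max(0, i - h)
        hi = min(T, i + h + 1)
        out[i] = np.percentile(block[lo:hi], q, axis=0)
    return out


def _normalize_block(F: np.ndarray, method: str, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalize columns of a (T, N) block; returns (out, degenerate_cols)."""
    F = np.asarray(F, dtype=np.float64)
    if method == "none":
        return F.copy(), np.zeros(F.shape[-1] if F.ndim > 1 else (), dtype=bool)
    if method == "zscore":
        mu = F.mean(axis=0)
        sd = F.std(axis=0)
        degen = sd == 0
        safe = np.where(degen, 1.0, sd)
        out = (F - mu) / safe
        if F.ndim > 1:
            out[:, degen] = 0.0
        elif degen:
            out[:] = 0.0
        return out, degen
    # dff_running_percentile
    if window < 2:
        raise ParameterError("norm window must be >= 2 for dff_running_percentile")
    f0 = _running_percentile(F, window, q=10.0)
    gmean = F.mean()
    eps = 1e-6 * abs(gmean) if gmean != 0 else 1e-6
    out = (F - f0) / np.maximum(f0, eps)
    degen = out.std(axis=0) == 0
    return out, degen


def normalize_trace(
    f: np.ndarray, method: str = "dff_running_percentile", window: int = 10
) -> NormalizedTrace:
    """Normalize a 1D fluorescence trace.

    ``dff_running_percentile``: F0 is the running 10th percentile over a
    centered window of half-width ``window`` (shrunk at the edges);
    output is (F - F0)/max(F0, eps) with eps = 1e-6 x the global mean
    guarding the division.
    ``zscore``: global (F - mean)/SD.  ``none``: identity.

    A zero-variance result is returned as an all-zero trace with the
    degenerate flag set — never an exception, so maps are not poisoned.
    """
    if method not in _NORM_METHODS:
        raise ParameterError(f"unknown normalization {method!r}")
    f = np.asarray(f, dtype=np.float64)
    out, degen = _normalize_block(f[:, None], method, window)
    degen = bool(degen[0])
    vals = out[:, 0]
    if degen:
        vals = np.zeros_like(vals)
    return NormalizedTrace(vals, degen)


# ---------------------------------------------------------------------------
# lagged Pearson statistics
# ---------------------------------------------------------------------------

def _stim_values(s) -> np.ndarray:
    if isinstance(s, StimVector):
        return s.values.astype(np.float64)
    return np.asarray(s, dtype=np.float64)


def _check_lag(T: int, k: int) -> None:
    if k < 0:
        raise LagError(f"lag must be >= 0; got {k}")
    if T - k < MIN_OVERLAP:
        raise LagError(
            f"lag {k} leaves overlap {T - k} < minimum {MIN_OVERLAP} (T={T})"
        )


def _pearson_block(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of a 1D x against every column of (L, N) Y; degenerate -> 0."""
    x = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((x ** 2).sum())
    sy = np.sqrt((Yc ** 2).sum(axis=0))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ Yc) / denom
    r[denom == 0] = 0.0
    return np.clip(r, -1.0, 1.0)


def pearson_at_lag(f, s, k: int) -> float:
    """Pearson r between stimulus and fluorescence delayed by k frames.

    Pairs are ``(s[t], f[t + k])`` over the overlap of length T - k
    (fluorescence lags stimulus).  Zero-variance overlaps give 0.0.
    """
    fv = np.asarray(f, dtype=np.float64)
    sv = _stim_values(s)
    if fv.shape != sv.shape or fv.ndim != 1:
        raise ShapeError("trace and stimulus must be 1D and equal length")
    T = fv.size
    _check_lag(T, k)
    return float(_pearson_block(sv[: T - k], fv[k:, None])[0])


def _lag_matrix(F: np.ndarray, s: np.ndarray, K: int) -> np.ndarray:
    """(K+1, N) matrix of per-lag Pearson r for every column of (T, N) F."""
    T = F.shape[0]
    _check_lag(T, K)
    return np.stack([_pearson_block(s[: T - k], F[k:]) for k in range(K + 1)])


def cumulative_xcorr(f, s, K: int) -> float:
    """Sum of per-lag Pearson coefficients over lags 0..K inclusive."""
    fv = np.asarray(f, dtype=np.float64)
    sv = _stim_values(s)
    if fv.shape != sv.shape:
        raise ShapeError("trace and stimulus must be equal length")
    return float(_lag_matrix(fv[:, None], sv, K).sum(axis=0)[0])


def peak_xcorr(f, s, K: int) -> tuple[float, int]:
    """(max r over lags 0..K, lag of the max); ties go to the smallest lag."""
    fv = np.asarray(f, dtype=np.float64)
    sv = _stim_values(s)
    if fv.shape != sv.shape:
        raise ShapeError("trace and stimulus must be equal length")
    r = _lag_matrix(fv[:, None], sv, K)[:, 0]
    k = int(np.argmax(r))  # argmax returns the first (smallest-lag) maximum
    return float(r[k]), k


# ---------------------------------------------------------------------------
# spatial pre-averaging
# ---------------------------------------------------------------------------

def xy_boxmean(stack: Hyperstack, m: int) -> Hyperstack:
    """Replace each voxel by its in-plane (2m+1)^2 neighborhood mean.

    The neighborhood shrinks at image borders (mean over in-bounds pixels
    only); z, t, and channels are untouched.  m = 0 is the identity.
    """
    if m < 0:
        raise ParameterError("xy halfwidth must be >= 0")
    if m == 0:
        return stack
    w = 2 * m + 1
    data = stack.data.astype(np.float64)
    size = (1, 1, 1, w, w)
    sums = ndimage.uniform_filter(data, size=size, mode="constant", cval=0.0) * (w * w)
    ones = np.ones(stack.shape[-2:], dtype=np.float64)
    counts = ndimage.uniform_filter(ones, size=(w, w), mode="constant", cval=0.0) * (w * w)
    out = (sums / counts).astype(np.float32)
    return stack.with_data(out)


# ---------------------------------------------------------------------------
# map, null, quantification
# ---------------------------------------------------------------------------

def _prepare_block(
    stack: Hyperstack, c: int, params: CorrelationParams
) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Boxmean + normalize; returns ((T, N) block, degenerate cols, (Z,Y,X))."""
    C, T, Z, Y, X = stack.shape
    if not 0 <= c < C:
        raise ShapeError(f"channel {c} outside [0, {C})")
    sub = xy_boxmean(stack, params.xy_halfwidth)
    F = sub.data[c].reshape(T, -1).astype(np.float64)
    F, degen = _normalize_block(F, params.normalization, params.norm_window)
    return F, degen, (Z, Y, X)


def _block_statistic(F: np.ndarray, s: np.ndarray, params: CorrelationParams):
    lags = _lag_matrix(F, s, params.lag_window_frames)
    if params.mode == "cumulative":
        return lags.sum(axis=0), None
    k_at = np.argmax(lags, axis=0)
    return lags.max(axis=0), k_at.astype(np.int64)


def correlation_map(
    stack: Hyperstack,
    s,
    c: int,
    params: CorrelationParams,
    mask: np.ndarray | None = None,
) -> CorrelationMap:
    """Voxel-by-voxel lagged-correlation map of one channel.

    ``s`` is a :class:`~voxcorr.sync.StimVector` or array of length T.
    Voxels outside ``mask`` (a (Z, Y, X) boolean volume) are set to 0 and
    excluded from any downstream statistics.  If the stimulus itself has
    zero variance every voxel is degenerate and the map is all zero with
    the global degenerate flag set.
    """
    sv = _stim_values(s)
    T = stack.n_stacks
    if sv.shape != (T,):
        raise ShapeError(f"stimulus length {sv.shape} != T = {T}")
    F, degen_cols, zyx = _prepare_block(stack, c, params)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != zyx:
            raise ShapeError(f"mask shape {mask.shape} != volume shape {zyx}")
    stim_degenerate = np.std(sv) == 0
    if stim_degenerate:
        values = np.zeros(zyx)
        return CorrelationMap(values, params, mask=mask, degenerate=True)
    stat, k_at = _block_statistic(F, sv, params)
    stat[degen_cols] = 0.0
    values = stat.reshape(zyx)
    lag_at = k_at.reshape(zyx) if k_at is not None else None
    if mask is not None:
        values = np.where(mask, values, 0.0)
        if lag_at is not None:
            lag_at = np.where(mask, lag_at, 0)
    return CorrelationMap(values, params, mask=mask, lag_at_peak=lag_at)


@dataclass
class NullResult:
    """Pooled circular-shift null values, detection threshold, per-voxel p."""

    null_values: np.ndarray
    threshold: float
    p_values: np.ndarray
    offsets: np.ndarray


def shift_null(
    stack: Hyperstack,
    s,
    c: int,
    params: CorrelationParams,
    mask: np.ndarray | None = None,
    observed: CorrelationMap | None = None,
) -> NullResult:
    """Calibrate a detection threshold by circular shifts of the stimulus.

    ``n_null`` random rotations of s by offsets uniform in
    [K+1, T-K-1] (preserving stimulus autocorrelation while breaking
    stimulus-locked alignment) are each scored on a random subsample of
    in-mask voxels (``null_subsample``, or all voxels if fewer).  The
    pooled ``null_percentile`` is the threshold; per-voxel p is the
    fraction of pooled null values >= the observed statistic.
    """
    if params.n_null < 1:
        raise ParameterError("n_null must be >= 1 for shift_null")
    sv = _stim_values(s)
    T = stack.n_stacks
    if sv.shape != (T,):
        raise ShapeError(f"stimulus length {sv.shape} != T = {T}")
    K = params.lag_window_frames
    lo, hi = K + 1, T - K - 1
    if hi < lo or (hi - lo + 1) < min(params.n_null, 2):
        raise ParameterError(
            f"insufficient shift space: offsets [{lo}, {hi}] for n_null={params.n_null}"
        )
    rng = np.random.default_rng(params.seed)
    F, degen_cols, zyx = _prepare_block(stack, c, params)
    n_vox = F.shape[1]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != zyx:
            raise ShapeError(f"mask shape {mask.shape} != volume shape {zyx}")
        candidates = np.flatnonzero(mask.ravel())
    else:
        candidates = np.arange(n_vox)
    if candidates.size == 0:
        raise MaskError("analysis mask is empty")
    n_sub = min(params.null_subsample, candidates.size)
    sub = rng.choice(candidates, size=n_sub, replace=False)
    Fsub = F[:, sub]
    offsets = rng.integers(lo, hi + 1, size=params.n_null)
    pooled = np.empty((params.n_null, n_sub))
    for i, off in enumerate(offsets):
        stat, _ = _block_statistic(Fsub, np.roll(sv, off), params)
        pooled[i] = stat
    null_values = pooled.ravel()
    threshold = float(np.percentile(null_values, params.null_percentile))
    if observed is None:
        observed = correlation_map(stack, s, c, params, mask=mask)
    sorted_null = np.sort(null_values)
    obs = observed.values.ravel()
    # p = fraction of null >= observed
    p = 1.0 - np.searchsorted(sorted_null, obs, side="left") / sorted_null.size
    p_values = p.reshape(zyx)
    return NullResult(
        null_values=null_values,
        threshold=threshold,
        p_values=p_values,
        offsets=offsets,
    )


def responding_volume(
    cmap: CorrelationMap, threshold: float
) -> tuple[float, list[tuple[tuple[int, int, int], float]]]:
    """Fraction and list of suprathreshold voxels.

    Returns ``(fraction, voxels)`` where fraction counts in-mask voxels
    with statistic strictly above threshold over the in-mask total, and
    ``voxels`` lists ((z, y, x), value) sorted by descending statistic.
    """
    if not math.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    values = cmap.values
    if cmap.mask is not None:
        mask = np.asarray(cmap.mask, dtype=bool)
        if not mask.any():
            raise MaskError("analysis mask is empty")
    else:
        mask = np.ones(values.shape, dtype=bool)
    above = (values > threshold) & mask
    fraction = above.sum() / mask.sum()
    zz, yy, xx = np.nonzero(above)
    vals = values[zz, yy, xx]
    order = np.argsort(-vals)
    voxels = [
        ((int(zz[i]), int(yy[i]), int(xx[i])), float(vals[i])) for i in order
    ]
    return float(fraction), voxels
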