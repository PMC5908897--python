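"""Multi-ROI trace extraction, normalization, overlays, and activity masks.

Batch re-implementation of interactive multi-ROI profiling: place any
number of rectangle/ellipse/polygon/mask ROIs on a hyperstack, extract the
mean-intensity trace of each along t (or z), optionally min/max-normalize,
overlay a running average and an externally loaded stimulus/ephys trace,
and export a CSV table plus a rendered figure.

A pixel belongs to an ellipse or polygon ROI iff its *center* lies inside
the shape.  Trace sample i represents the start time of stack i, i.e.
``i * stack_period_s``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from .errors import (
    CoverageError,
    DegenerateTraceError,
    ParameterError,
    ParseError,
    RoiError,
    TimeError,
)
from .hyperstack import Hyperstack

__all__ = [
    "Roi",
    "Trace",
    "extract_trace",
    "normalize_minmax",
    "running_average",
    "load_external_trace",
    "resample_to_stack",
    "activity_mask",
    "multi_roi_profile",
    "load_rois",
]


@dataclass
class Roi:
    """A 2D region of interest pinned to a plane (or averaged over z).

    kind/geometry:
      - ``rect``:    (x0, y0, x1, y1), half-open pixel bounds
      - ``ellipse``: (cx, cy, rx, ry) in pixel units
      - ``polygon``: sequence of (x, y) vertices
      - ``mask``:    2D boolean array of shape (Y, X)

    ``z`` is a plane index or ``"all"`` (mean over z); ``c`` the channel.
    """

    kind: str
    geometry: object
    z: int | str = 0
    c: int = 0
    label: str = ""

    def pixels(self, shape_yx: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Rasterize to (rows, cols) index arrays; pixel-center membership."""
        Y, X = shape_yx
        if self.kind == "rect":
            x0, y0, x1, y1 = (int(v) for v in self.geometry)
            if not (0 <= x0 < x1 <= X and 0 <= y0 < y1 <= Y):
                raise RoiError(
                    f"rect ({x0},{y0},{x1},{y1}) outside or empty for image {X}x{Y}"
                )
            yy, xx = np.mgrid[y0:y1, x0:x1]
            return yy.ravel(), xx.ravel()
        if self.kind == "ellipse":
            cx, cy, rx, ry = (float(v) for v in self.geometry)
            if rx <= 0 or ry <= 0:
                raise RoiError("ellipse radii must be > 0")
            yy, xx = np.mgrid[0:Y, 0:X]
            inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        elif self.kind == "polygon":
            verts = np.asarray(self.geometry, dtype=float)
            if verts.ndim != 2 or verts.shape[0] < 3:
                raise RoiError("polygon needs >= 3 (x, y) vertices")
            yy, xx = np.mgrid[0:Y, 0:X]
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            inside = MplPath(verts).contains_points(pts).reshape(Y, X)
        elif self.kind == "mask":
            inside = np.asarray(self.geometry, dtype=bool)
            if inside.shape != (Y, X):
                raise RoiError(f"mask shape {inside.shape} != image shape {(Y, X)}")
        else:
            raise RoiError(f"unknown ROI kind {self.kind!r}")
        rows, cols = np.nonzero(inside)
        if rows.size == 0:
            raise RoiError(f"ROI {self.label or self.kind!r} rasterizes to zero pixels")
        return rows, cols


@dataclass
class Trace:
    """A 1D sampled signal.

    ``dt_s`` is seconds per sample for time profiles; for z profiles it
    carries the z spacing in micrometers instead (the axis is spatial).
    """

    values: np.ndarray
    dt_s: float
    label: str = ""
    normalized: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ParameterError("trace values must be a non-empty 1D array")
        if not self.dt_s > 0:
            raise ParameterError(f"dt_s must be > 0; got {self.dt_s}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt_s


def extract_trace(stack: Hyperstack, roi: Roi, axis: str = "t") -> Trace:
    """Mean-intensity trace of an ROI along t (default) or z.

    For ``axis="t"`` the value at stack index i is the mean over the ROI
    pixels (and over all z when ``roi.z == "all"``).  For ``axis="z"`` the
    ROI must be time-pinned via an integer index stored in ``roi.z``
    being ignored; the profile averages over t.
    """
    C, T, Z, Y, X = stack.shape
    if not 0 <= roi.c < C:
        raise RoiError(f"channel {roi.c} outside [0, {C})")
    rows, cols = roi.pixels((Y, X))
    chan = stack.data[roi.c].astype(np.float64)  # (T, Z, Y, X)
    if axis == "t":
        if roi.z == "all":
            vals = chan[:, :, rows, cols].mean(axis=(1, 2))
        else:
            zi = int(roi.z)
            if not 0 <= zi < Z:
                raise RoiError(f"plane {zi} outside [0, {Z})")
            vals = chan[:, zi, rows, cols].mean(axis=1)
        return Trace(vals, dt_s=stack.stack_period_s, label=roi.label)
    if axis == "z":
        vals = chan[:, :, rows, cols].mean(axis=(0, 2))
        return Trace(vals, dt_s=stack.voxel_size_um[2], label=roi.label)
    raise ParameterError(f"axis must be 't' or 'z'; got {axis!r}")


def normalize_minmax(trace: Trace) -> Trace:
    """Rescale to [0, 1] so the minimum maps to 0 and the maximum to 1."""
    lo = trace.values.min()
    hi = trace.values.max()
    if hi == lo:
        raise DegenerateTraceError(
            f"trace {trace.label!r} is constant; min/max normalization undefined"
        )
    return replace(
        trace, values=(trace.values - lo) / (hi - lo), normalized=True
    )


def running_average(trace: Trace, window: int) -> Trace:
    """Centered moving mean with edge windows shrunk to available samples."""
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be a positive odd integer; got {window}")
    if window == 1:
        return replace(trace, values=trace.values.copy())
    h = window // 2
    v = trace.values
    csum = np.concatenate(([0.0], np.cumsum(v)))
    n = v.size
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(trace, values=out)


def load_external_trace(path, dt_s: float | None = None) -> Trace:
    """Load a 1- or 2-column ASCII trace (stimulus, ephys, ...).

    Two columns are interpreted as (time_s, value) with dt inferred from
    the median time step; one column requires ``dt_s``.  Lines starting
    with ``#`` are ignored; any other non-numeric content is an error.
    """
    try:
        table = pd.read_csv(
            path, sep=r"[\s,;]+", engine="python", comment="#", header=None,
        ).to_numpy(dtype=np.float64)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse trace file {path}: {exc}") from exc
    if table.ndim != 2 or table.shape[1] not in (1, 2):
        raise ParseError(f"trace file must have 1 or 2 columns; got {table.shape}")
    label = Path(path).stem
    if table.shape[1] == 2:
        t = table[:, 0]
        diffs = np.diff(t)
        if t.size < 2 or (diffs <= 0).any():
            raise TimeError("time column must be strictly increasing")
        return Trace(table[:, 1], dt_s=float(np.median(diffs)), label=label)
    if dt_s is None:
        raise ParseError("single-column trace requires dt_s from the caller")
    return Trace(table[:, 0], dt_s=dt_s, label=label)


def _is_binary_like(values: np.ndarray) -> bool:
    # exactly two levels after rounding: a TTL-like on/off trace.  A
    # constant trace is *not* binary-like — it resamples to its own mean.
    return np.unique(np.round(values, 3)).size == 2


def resample_to_stack(ext: Trace, n_stacks: int, stack_period_s: float) -> Trace:
    """Resample an external trace onto the stack time base.

    Binary-like traces (<= 2 distinct values after rounding to 3 decimals)
    yield 1 for a stack iff any source sample within that stack interval
    exceeds half the trace maximum; continuous traces yield the interval
    mean.  The trace must cover the full acquisition.
    """
    if n_stacks < 1 or not stack_period_s > 0:
        raise ParameterError("n_stacks >= 1 and stack_period_s > 0 required")
    duration = ext.values.size * ext.dt_s
    needed = n_stacks * stack_period_s
    if duration + 1e-9 < needed:
        raise CoverageError(
            f"external trace covers {duration:.3f}s < acquisition {needed:.3f}s"
        )
    sample_times = np.arange(ext.values.size) * ext.dt_s
    bins = np.floor(sample_times / stack_period_s).astype(np.int64)
    keep = bins < n_stacks
    bins = bins[keep]
    vals = ext.values[keep]
    if _is_binary_like(ext.values):
        thresh = 0.5 * ext.values.max()
        out = np.zeros(n_stacks)
        np.add.at(out, bins, (vals > thresh).astype(float))
        out = (out > 0).astype(np.float64)
    else:
        sums = np.zeros(n_stacks)
        counts = np.zeros(n_stacks)
        np.add.at(sums, bins, vals)
        np.add.at(counts, bins, 1.0)
        if (counts == 0).any():
            raise CoverageError("some stack intervals contain no source samples")
        out = sums / counts
    return Trace(out, dt_s=stack_period_s, label=ext.label)


def activity_mask(
    stack: Hyperstack,
    c: int,
    t_window: tuple[int, int],
    k_sd: float,
) -> np.ndarray:
    """SD-threshold activity mask of a short time-average volume.

    The stacks in the half-open window are averaged into one (z, y, x)
    volume; a voxel is active when its windowed mean exceeds the
    whole-volume mean plus ``k_sd`` standard deviations of that same
    volume (e.g. a 2 s average thresholded at 4 SD).
    """
    C, T = stack.shape[:2]
    lo, hi = t_window
    if not 0 <= c < C:
        raise ParameterError(f"channel {c} outside [0, {C})")
    if not (0 <= lo < hi <= T):
        raise ParameterError(f"t_window [{lo},{hi}) invalid for T={T}")
    if not k_sd > 0:
        raise ParameterError("k_sd must be > 0")
    vol = stack.data[c, lo:hi].astype(np.float64).mean(axis=0)
    thresh = vol.mean() + k_sd * vol.std()
    return vol > thresh


def load_rois(path) -> list[Roi]:
    """Read ROI definitions from a JSON file (list of Roi field dicts)."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"cannot parse ROI file {path}: {exc}") from exc
    if not isinstance(raw, list):
        raise ParseError("ROI file must contain a JSON list")
    return [
        Roi(
            kind=d["kind"],
            geometry=d["geometry"],
            z=d.get("z", 0),
            c=d.get("c", 0),
            label=d.get("label", f"roi{i}"),
        )
        for i, d in enumerate(raw)
    ]


def multi_roi_profile(
    stack: Hyperstack,
    rois: Sequence[Roi],
    normalize: bool = False,
    running_window: int | None = None,
    external: Trace | None = None,
    csv_path=None,
    figure_path=None,
) -> pd.DataFrame:
    """Extract one trace per ROI with optional companions; tabulate/plot.

    A constant-trace ROI under normalization is reported degenerate (its
    raw trace is kept, flagged in the ``degenerate_rois`` DataFrame attr)
    without affecting the other ROIs.  Running averages are added as
    ``<label>_ra`` columns; the external trace, resampled to the stack
    time base, as ``external``.
    """
    if not rois:
        raise RoiError("at least one ROI required")
    traces: list[Trace] = []
    degenerate: list[str] = []
    for roi in rois:
        tr = extract_trace(stack, roi, axis="t")
        if normalize:
            try:
                tr = normalize_minmax(tr)
            except DegenerateTraceError:
                degenerate.append(tr.label)
                tr = replace(tr, degenerate=True)
        traces.append(tr)

    table = pd.DataFrame({"time_s": traces[0].times})
    for tr in traces:
        table[tr.label] = tr.values
    if running_window is not None:
        for tr in traces:
            table[f"{tr.label}_ra"] = running_average(tr, running_window).values
    if external is not None:
        ext = resample_to_stack(external, stack.n_stacks, stack.stack_period_s)
        table["external"] = ext.values
    table.attrs["degenerate_rois"] = degenerate

    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if figure_path is not None:
        _render_profile(table, [tr.label for tr in traces], figure_path)
    return table


def _render_profile(table: pd.DataFrame, labels: list[str], figure_path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 1.2 * max(1, len(labels))))
    offset = 0.0
    for lbl in labels:
        v = table[lbl].to_numpy()
        span = np.ptp(v) or 1.0
        ax.plot(table["time_s"], (v - v.min()) / span + offset, lw=0.8, label=lbl)
        ra = f"{lbl}_ra"
        if ra in table:
            r = table[ra].to_numpy()
            ax.plot(table["time_s"], (r - v.min()) / span + offset, color="k", lw=0.8)
        offset += 1.2
    if "external" in table:
        e = table["external"].to_numpy()
        span = np.ptp(e) or 1.0
        ax.plot(table["time_s"], (e - e.min()) / span + offset, color="r", lw=0.8,
                label="external")
    ax.set_xlabel("time (s)")
    ax.set_yticks([])
    ax.legend(loc="upper right", fontsize="x-small")
    fig.tight_layout()
    fig.savefig(figure_path, dpi=120)
    plt.close(fig)
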