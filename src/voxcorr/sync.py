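"""Imaging/electrophysiology synchronization from dual-channel state traces.

Acquisition timing is reconstructed post hoc from a two-channel recording
(typically 1 kHz): the Y-galvanometer position feedback, whose sawtooth
ramps delimit individual frame scans, and a split-off of the stimulator TTL
trigger, whose brief (2-3 sample) spikes mark stimulation episodes.  From
frame starts and an acquisition geometry (planes per z-stack, overhead
frames, lines per frame) every stimulation sample is mapped to a
(stack t, plane z, approximate line y) coordinate, and stimulation events
are aggregated into a per-stack stimulus vector for correlation analysis.

TTL pulse amplitudes after 1 kHz sub-sampling vary widely (on the order of
0.1-2 V for a 5 V pulse lasting tens of microseconds) but remain far above
baseline noise, so detection is threshold-on-local-maximum relative to the
channel median, not to an assumed 0 V baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (
    NoFramesError,
    ParameterError,
    ParseError,
    PreAcquisitionError,
    RangeError,
)

__all__ = [
    "SyncRecording",
    "AcquisitionGeometry",
    "StimEvent",
    "StimVector",
    "read_sync_file",
    "detect_frame_starts",
    "detect_ttl_events",
    "map_sample_to_stack",
    "locate_events",
    "build_stim_vector",
]


@dataclass
class SyncRecording:
    """Dual-channel sampled state voltages (galvo feedback + stim TTL)."""

    galvo_y: np.ndarray
    stim_ttl: np.ndarray
    fs_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.galvo_y = np.asarray(self.galvo_y, dtype=np.float64)
        self.stim_ttl = np.asarray(self.stim_ttl, dtype=np.float64)
        if self.galvo_y.shape != self.stim_ttl.shape or self.galvo_y.ndim != 1:
            raise ParameterError("galvo_y and stim_ttl must be 1D and equal length")
        if not self.fs_hz > 0:
            raise ParameterError(f"fs_hz must be > 0; got {self.fs_hz}")

    @property
    def n_samples(self) -> int:
        return self.galvo_y.size


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Frame budget of one z-stack.

    ``planes_per_stack`` imaged focal planes plus ``extra_frames_per_stack``
    non-imaging overhead frames (piezo return, bidirectional-scan padding)
    make up the per-stack frame budget.
    """

    planes_per_stack: int
    extra_frames_per_stack: int = 0
    lines_per_frame: int = 1

    def __post_init__(self) -> None:
        if self.planes_per_stack < 1:
            raise ParameterError("planes_per_stack must be >= 1")
        if self.extra_frames_per_stack < 0:
            raise ParameterError("extra_frames_per_stack must be >= 0")
        if self.lines_per_frame < 1:
            raise ParameterError("lines_per_frame must be >= 1")

    @property
    def frames_per_stack(self) -> int:
        return self.planes_per_stack + self.extra_frames_per_stack


@dataclass(frozen=True)
class StimEvent:
    """One detected stimulation episode located in acquisition coordinates.

    ``z`` is -1 when the event fell in an overhead (non-imaging) frame;
    ``y`` is a linear within-frame estimate (-1 if not resolved) and is
    approximate by construction.
    """

    sample_index: int
    time_s: float
    t: int
    z: int
    y: int = -1
    peak_amplitude_v: float = float("nan")


@dataclass
class StimVector:
    """Per-stack stimulus series; ``mode`` is ``"binary"`` or ``"count"``."""

    values: np.ndarray
    mode: str = "binary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.mode not in ("binary", "count"):
            raise ParameterError(f"mode must be binary|count; got {self.mode!r}")
        if self.mode == "binary" and not np.isin(self.values, (0, 1)).all():
            raise ParameterError("binary stimulus vector must contain only 0/1")
        if (self.values < 0).any():
            raise ParameterError("stimulus vector values must be >= 0")

    def __len__(self) -> int:
        return self.values.size


def read_sync_file(path, fs_hz: float = 1000.0) -> SyncRecording:
    """Load a 2- or 3-column delimited ASCII recording.

    Columns are ``galvo stim`` or ``time galvo stim``; ``#`` lines are
    comments.  With a time column the sampling rate is inferred from the
    median time step.
    """
    try:
        table = pd.read_csv(
            path, sep=r"[\s,;]+", engine="python", comment="#", header=None,
        ).to_numpy(dtype=np.float64)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse sync file {path}: {exc}") from exc
    if table.ndim != 2 or table.shape[1] not in (2, 3):
        raise ParseError(f"sync file must have 2 or 3 columns; got shape {table.shape}")
    if table.shape[1] == 3:
        t = table[:, 0]
        dt = np.median(np.diff(t))
        if not dt > 0:
            raise ParseError("time column must be strictly increasing")
        fs_hz = 1.0 / dt
        galvo, ttl = table[:, 1], table[:, 2]
    else:
        galvo, ttl = table[:, 0], table[:, 1]
    return SyncRecording(galvo_y=galvo, stim_ttl=ttl, fs_hz=fs_hz)


def detect_frame_starts(
    rec: SyncRecording,
    min_period_samples: int = 2,
    k_mad: float = 8.0,
) -> np.ndarray:
    """Locate the first sample of every frame scan in the galvo trace.

    A frame boundary is a negative-going excursion of the first difference
    exceeding ``k_mad`` times the MAD of the difference (falling back to
    half the deepest excursion when the MAD is zero, as on noiseless
    synthetic ramps).  Consecutive negative samples are merged into one
    flyback; the frame start is the sample following it.  A start at index
    0 is prepended when the recording opens mid-ramp.
    """
    g = rec.galvo_y
    if g.size < 2 or np.ptp(g) == 0:
        raise NoFramesError("galvo trace is flat; no frame scans detectable")
    d = np.diff(g)
    dev = d - np.median(d)
    mad = np.median(np.abs(dev))
    # float rounding leaves a vanishing but nonzero MAD on noiseless ramps
    if mad > 1e-9 * np.ptp(g):
        thresh = k_mad * mad
    else:
        deepest = -dev.min()
        if deepest <= 0:
            # monotonic single ramp, no flyback at all
            return np.array([0], dtype=np.int64)
        thresh = 0.5 * deepest
    below = dev < -thresh
    if not below.any():
        return np.array([0], dtype=np.int64)
    # group consecutive below-threshold samples into flybacks
    idx = np.flatnonzero(below)
    group_ends = idx[np.flatnonzero(np.diff(idx) > 1)].tolist() + [idx[-1]]
    starts = [int(e) + 1 for e in group_ends if e + 1 < g.size]
    # refractory merge
    merged: list[int] = []
    for s in starts:
        if not merged or s - merged[-1] >= min_period_samples:
            merged.append(s)
    if merged and merged[0] >= min_period_samples:
        merged.insert(0, 0)
    elif not merged:
        merged = [0]
    return np.asarray(merged, dtype=np.int64)


def detect_ttl_events(
    rec: SyncRecording,
    min_amplitude_v: float = 0.05,
    min_separation_samples: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Find stimulation pulses on the TTL channel.

    Returns ``(sample_indices, amplitudes_v)`` of local maxima exceeding
    ``baseline + min_amplitude_v``, where baseline is the channel median
    (so a constant DC level on the channel is irrelevant).  Maxima closer
    than ``min_separation_samples`` are merged, keeping the tallest; edge
    samples can be peaks.
    """
    if not min_amplitude_v > 0:
        raise ParameterError("min_amplitude_v must be > 0")
    ttl = rec.stim_ttl
    baseline = float(np.median(ttl))
    # pad so maxima at the first/last sample register as peaks
    padded = np.concatenate(([-np.inf], ttl, [-np.inf]))
    peaks, props = find_peaks(
        padded,
        height=baseline + min_amplitude_v,
        distance=max(1, min_separation_samples),
    )
    indices = peaks - 1
    amplitudes = props["peak_heights"] - baseline
    return indices.astype(np.int64), amplitudes.astype(np.float64)


def map_sample_to_stack(
    frame_starts: np.ndarray,
    geom: AcquisitionGeometry,
    sample_index: int,
) -> tuple[int, int, int]:
    """Map a recording sample to (stack t, plane z, line y).

    The frame index is the count of frame starts at or before the sample,
    minus one; ``z`` is -1 for overhead frames; ``y`` is the linear
    within-frame line estimate (approximate).
    """
    frame_starts = np.asarray(frame_starts)
    if frame_starts.size == 0:
        raise NoFramesError("frame_starts is empty")
    if sample_index < frame_starts[0]:
        raise PreAcquisitionError(
            f"sample {sample_index} precedes first frame start {frame_starts[0]}"
        )
    f = int(np.searchsorted(frame_starts, sample_index, side="right")) - 1
    B = geom.frames_per_stack
    t = f // B
    within = f % B
    z = within if within < geom.planes_per_stack else -1
    # within-frame fraction: use next start, or median period for the last frame
    start = int(frame_starts[f])
    if f + 1 < frame_starts.size:
        dur = int(frame_starts[f + 1]) - start
    else:
        dur = int(np.median(np.diff(frame_starts))) if frame_starts.size > 1 else 0
    if dur > 0:
        y = int(geom.lines_per_frame * (sample_index - start) / dur)
        y = min(y, geom.lines_per_frame - 1)
    else:
        y = -1
    return t, z, y


def locate_events(
    rec: SyncRecording,
    geom: AcquisitionGeometry,
    min_amplitude_v: float = 0.05,
    min_separation_samples: int = 5,
    min_period_samples: int = 2,
) -> list[StimEvent]:
    """Full pipeline: detect frames + TTL pulses, return located events."""
    starts = detect_frame_starts(rec, min_period_samples=min_period_samples)
    indices, amps = detect_ttl_events(
        rec, min_amplitude_v=min_amplitude_v,
        min_separation_samples=min_separation_samples,
    )
    events = []
    for i, a in zip(indices, amps):
        t, z, y = map_sample_to_stack(starts, geom, int(i))
        events.append(
            StimEvent(
                sample_index=int(i),
                time_s=float(i) / rec.fs_hz,
                t=t, z=z, y=y,
                peak_amplitude_v=float(a),
            )
        )
    return events


def build_stim_vector(
    events: list[StimEvent],
    n_stacks: int,
    mode: str = "binary",
) -> StimVector:
    """Aggregate located events into a per-stack stimulus vector.

    Events in overhead frames (z = -1) still count toward their stack: the
    stimulus time matters for correlation even if no plane was imaging.
    """
    counts = np.zeros(n_stacks, dtype=np.int64)
    for ev in events:
        if not 0 <= ev.t < n_stacks:
            raise RangeError(f"event stack index {ev.t} outside [0, {n_stacks})")
        counts[ev.t] += 1
    if mode == "binary":
        return StimVector(values=(counts > 0).astype(np.int64), mode="binary")
    return StimVector(values=counts, mode="count")


def events_to_frame(events: list[StimEvent]) -> pd.DataFrame:
    """Tabulate events as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "sample": ev.sample_index,
                "time_s": ev.time_s,
                "t": ev.t,
                "z": ev.z,
                "y": ev.y,
                "amplitude_v": ev.peak_amplitude_v,
            }
            for ev in events
        ],
        columns=["sample", "time_s", "t", "z", "y", "amplitude_v"],
    )
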