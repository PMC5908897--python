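"""Synthetic 5D Ca2+ stacks, stimulation protocols, and sync recordings.

The generator emulates the experimental regime the analysis targets:
GCaMP6f-expressing astrocytes imaged volumetrically at ~2 Hz stack rate,
with a high level of spontaneous (endogenous) transients everywhere, a
small contiguous "responder" blob (~0.5% of the volume, standing in for a
reliably responding gliapil compartment) that follows electrical
stimulation episodes with per-trial response failures and jittered delays,
additive Gaussian noise, and — on the electrophysiology side — a 1 kHz
dual-channel state recording (galvo sawtooth + sub-sampled TTL pulses of
0.1-2 V lasting 2-3 samples).

Every stochastic quantity derives from a single mandatory seed, so stacks,
ground truth, and sync traces are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DurationError, ParameterError, TruthError
from .hyperstack import Hyperstack
from .sync import AcquisitionGeometry, StimVector, SyncRecording

__all__ = [
    "Protocol",
    "SynthConfig",
    "GroundTruth",
    "make_sparse_protocol",
    "make_train_protocol",
    "default_config",
    "simulate_stack",
    "simulate_sync",
    "sync_ground_truth",
    "stim_vector_from_protocol",
    "score_detection",
]


@dataclass(frozen=True)
class Protocol:
    """A stimulation protocol: episode times plus train composition.

    ``event_times_s`` lists one entry per *episode*; an episode with
    ``pulses_per_event[i] > 1`` is a brief train at ``intra_train_hz``.
    """

    event_times_s: tuple[float, ...]
    pulses_per_event: tuple[int, ...] = ()
    intra_train_hz: float = 100.0

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times_s, dtype=float)
        if times.size and ((np.diff(times) <= 0).any() or times[0] < 0):
            raise ParameterError("event times must be strictly increasing and >= 0")
        if not self.pulses_per_event:
            object.__setattr__(
                self, "pulses_per_event", tuple([1] * times.size)
            )
        if len(self.pulses_per_event) != times.size:
            raise ParameterError("pulses_per_event length must match event count")

    @property
    def n_events(self) -> int:
        return len(self.event_times_s)

    @property
    def duration_s(self) -> float:
        if not self.event_times_s:
            return 0.0
        last = self.event_times_s[-1]
        extra = (self.pulses_per_event[-1] - 1) / self.intra_train_hz
        return last + extra

    def pulse_times_s(self) -> np.ndarray:
        """Expand trains into individual pulse times."""
        out = []
        for t0, n in zip(self.event_times_s, self.pulses_per_event):
            out.extend(t0 + np.arange(n) / self.intra_train_hz)
        return np.asarray(out)


def make_sparse_protocol(
    rate_hz: float = 0.05,
    events_per_epoch: int = 5,
    n_epochs: int = 3,
    gap_s: float = 120.0,
) -> Protocol:
    """Sparse single-pulse protocol: epochs of low-rate episodes.

    Defaults give three epochs of five episodes at 0.05 Hz (20 s spacing,
    100 s of stimulation per epoch) separated by 120 s quiescent gaps —
    15 episodes in total over ~9 minutes.  A 2x-sped-up variant is
    ``make_sparse_protocol(rate_hz=0.1, gap_s=60.0)``.
    """
    if rate_hz <= 0 or events_per_epoch < 1 or n_epochs < 1 or gap_s < 0:
        raise ParameterError("invalid sparse-protocol parameters")
    spacing = 1.0 / rate_hz
    epoch_period = events_per_epoch * spacing + gap_s
    times = [
        e * epoch_period + j * spacing
        for e in range(n_epochs)
        for j in range(events_per_epoch)
    ]
    return Protocol(event_times_s=tuple(times))


def make_train_protocol(
    episode_spacing_s: float = 10.0,
    pulse_sequence: tuple[int, ...] = (1, 2, 3, 4, 5, 1, 2),
    n_epochs: int = 3,
    gap_s: float = 60.0,
    intra_train_hz: float = 100.0,
) -> Protocol:
    """Graded-train protocol: per epoch, one episode every 10 s with pulse
    counts 1, 2, 3, 4, 5, 1, 2 (100 Hz within trains), epochs separated by
    quiescent gaps."""
    if episode_spacing_s <= 0 or n_epochs < 1 or min(pulse_sequence) < 1:
        raise ParameterError("invalid train-protocol parameters")
    epoch_period = len(pulse_sequence) * episode_spacing_s + gap_s
    times: list[float] = []
    pulses: list[int] = []
    for e in range(n_epochs):
        for j, n in enumerate(pulse_sequence):
            times.append(e * epoch_period + j * episode_spacing_s)
            pulses.append(n)
    return Protocol(
        event_times_s=tuple(times),
        pulses_per_event=tuple(pulses),
        intra_train_hz=intra_train_hz,
    )


@dataclass(frozen=True)
class SynthConfig:
    """Stack-simulation parameters (see module docstring for the regime).

    Units: intensities in arbitrary fluorescence units; rates per
    voxel-hour; taus and jitter in seconds; response_amplitude_sd and
    spont_amplitude_sd in multiples of the noise SD.
    """

    shape: tuple[int, int, int, int, int] = (1, 600, 8, 32, 32)
    stack_period_s: float = 0.5
    baseline_f0: float = 100.0
    noise_sd: float = 10.0
    poisson_scale: float = 0.0
    spont_rate_per_voxel_hour: float = 6.0
    spont_amplitude_sd: float = 3.0
    tau_rise_s: float = 0.2
    tau_decay_s: float = 2.0
    responder_fraction: float = 0.005
    responder_center: tuple[int, int, int] | None = None
    responder_voxels: tuple[tuple[int, int, int], ...] | None = None
    response_prob: float = 0.8
    delay_jitter_s: float = 2.5
    response_amplitude_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape) or len(self.shape) != 5:
            raise ParameterError("shape must be 5 positive dimensions (C,T,Z,Y,X)")
        for name in ("stack_period_s", "baseline_f0"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        for name in (
            "noise_sd", "poisson_scale", "spont_rate_per_voxel_hour",
            "spont_amplitude_sd", "tau_rise_s", "tau_decay_s",
            "delay_jitter_s", "response_amplitude_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 <= self.responder_fraction <= 1:
            raise ParameterError("responder_fraction must be in [0, 1]")
        if not 0 <= self.response_prob <= 1:
            raise ParameterError("response_prob must be in [0, 1]")


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """The default recovery-benchmark configuration."""
    return replace(SynthConfig(seed=seed), **overrides)


@dataclass
class GroundTruth:
    """Planted truth for detector scoring."""

    responder_voxels: list[tuple[int, int, int]]
    responder_mask: np.ndarray
    trials: pd.DataFrame  # trial, time_s, responded, delay_s, amplitude
    spontaneous: pd.DataFrame  # z, y, x, onset_s, amplitude

    @property
    def planted_fraction(self) -> float:
        return len(self.responder_voxels) / self.responder_mask.size


# ---------------------------------------------------------------------------
# transient kinetics
# ---------------------------------------------------------------------------

def _kernel_peak(tau_rise: float, tau_decay: float) -> tuple[float, float]:
    """(t_peak, peak value) of (1 - exp(-t/tr)) * exp(-t/td)."""
    if tau_rise == 0:
        return 0.0, 1.0
    t_peak = tau_rise * math.log((tau_rise + tau_decay) / tau_rise)
    peak = (1 - math.exp(-t_peak / tau_rise)) * math.exp(-t_peak / tau_decay)
    return t_peak, peak


def transient(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Double-exponential Ca2+ transient, unit peak amplitude, 0 for t < 0."""
    _, peak = _kernel_peak(tau_rise, tau_decay)
    t = np.asarray(t, dtype=np.float64)
    with np.errstate(over="ignore"):
        rise = 1.0 - np.exp(-np.maximum(t, 0.0) / tau_rise) if tau_rise > 0 else 1.0
        v = rise * np.exp(-np.maximum(t, 0.0) / tau_decay)
    return np.where(t < 0, 0.0, v / peak)


def _responder_blob(
    shape_zyx: tuple[int, int, int],
    fraction: float,
    center: tuple[int, int, int] | None,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """Contiguous quasi-spherical blob of ~fraction of the volume."""
    Z, Y, X = shape_zyx
    n_target = max(1, round(fraction * Z * Y * X))
    if center is None:
        cz, cy, cx = Z // 2, Y // 2, X // 2
    else:
        cz, cy, cx = center
    zz, yy, xx = np.mgrid[0:Z, 0:Y, 0:X]
    d2 = (zz - cz) ** 2.0 + (yy - cy) ** 2.0 + (xx - cx) ** 2.0
    order = np.argsort(d2.ravel(), kind="stable")[:n_target]
    vox = np.column_stack(np.unravel_index(order, (Z, Y, X)))
    return [tuple(map(int, v)) for v in vox]


def simulate_stack(
    config: SynthConfig, protocol: Protocol
) -> tuple[Hyperstack, GroundTruth]:
    """Render a synthetic stack plus its ground truth.

    Each voxel trace is baseline + Poisson-timed spontaneous transients +
    (responders only) per-trial evoked transients with Bernoulli
    occurrence and uniform delay jitter + Gaussian noise; transients are
    double-exponential with shared kinetics.  Channel 0 carries the
    signal; any further channels are baseline + noise only.
    """
    C, T, Z, Y, X = config.shape
    duration = T * config.stack_period_s
    if protocol.duration_s > duration:
        raise DurationError(
            f"protocol spans {protocol.duration_s:.1f}s > acquisition {duration:.1f}s"
        )
    rng = np.random.default_rng(config.seed)
    n_vox = Z * Y * X
    times = np.arange(T) * config.stack_period_s

    F = np.full((T, n_vox), config.baseline_f0, dtype=np.float64)
    support_s = config.tau_rise_s + 8.0 * config.tau_decay_s
    support_frames = max(1, int(np.ceil(support_s / config.stack_period_s)))

    def add_transient(col: int, onset_s: float, amplitude: float) -> None:
        i0 = int(np.ceil(onset_s / config.stack_period_s - 1e-9))
        i1 = min(T, i0 + support_frames + 1)
        if i0 >= T:
            return
        F[i0:i1, col] += amplitude * transient(
            times[i0:i1] - onset_s, config.tau_rise_s, config.tau_decay_s
        )

    # spontaneous activity: Poisson count over the whole volume
    rate_per_s = config.spont_rate_per_voxel_hour / 3600.0
    lam = rate_per_s * n_vox * duration
    n_spont = int(rng.poisson(lam)) if lam > 0 else 0
    spont_cols = rng.integers(0, n_vox, size=n_spont)
    spont_onsets = rng.uniform(0.0, duration, size=n_spont)
    spont_amps = (
        config.spont_amplitude_sd * config.noise_sd * rng.uniform(0.5, 1.5, size=n_spont)
    )
    for col, onset, amp in zip(spont_cols, spont_onsets, spont_amps):
        add_transient(int(col), float(onset), float(amp))

    # responders and evoked activity
    if config.responder_voxels is not None:
        responders = [tuple(map(int, v)) for v in config.responder_voxels]
    elif config.responder_fraction > 0:
        responders = _responder_blob(
            (Z, Y, X), config.responder_fraction, config.responder_center, rng
        )
    else:
        responders = []
    resp_mask = np.zeros((Z, Y, X), dtype=bool)
    for z, y, x in responders:
        if not (0 <= z < Z and 0 <= y < Y and 0 <= x < X):
            raise ParameterError(f"responder voxel {(z, y, x)} outside volume")
        resp_mask[z, y, x] = True
    resp_cols = np.flatnonzero(resp_mask.ravel())

    trial_rows = []
    amp = config.response_amplitude_sd * config.noise_sd
    for i, t_ev in enumerate(protocol.event_times_s):
        responded = bool(rng.random() < config.response_prob) if responders else False
        delay = float(rng.uniform(0.0, config.delay_jitter_s))
        trial_rows.append(
            {
                "trial": i,
                "time_s": float(t_ev),
                "responded": responded,
                "delay_s": delay,
                "amplitude": amp if responded else 0.0,
            }
        )
        if responded:
            for col in resp_cols:
                add_transient(int(col), t_ev + delay, amp)

    # noise (optionally signal-scaled, approximating photon statistics)
    if config.noise_sd > 0 or config.poisson_scale > 0:
        sd = np.sqrt(config.noise_sd ** 2 + config.poisson_scale * np.maximum(F, 0))
        F += rng.standard_normal(F.shape) * sd

    data = np.zeros((C, T, Z, Y, X), dtype=np.float32)
    data[0] = F.reshape(T, Z, Y, X).astype(np.float32)
    for ch in range(1, C):
        extra = config.baseline_f0 + rng.standard_normal((T, Z, Y, X)) * config.noise_sd
        data[ch] = extra.astype(np.float32)

    stack = Hyperstack(
        data=data,
        voxel_size_um=(1.0, 1.0, 2.0),
        stack_period_s=config.stack_period_s,
        channel_labels=[f"ch{i}" for i in range(C)],
    )
    truth = GroundTruth(
        responder_voxels=responders,
        responder_mask=resp_mask,
        trials=pd.DataFrame(
            trial_rows, columns=["trial", "time_s", "responded", "delay_s", "amplitude"]
        ),
        spontaneous=pd.DataFrame(
            {
                "z": spont_cols // (Y * X),
                "y": (spont_cols // X) % Y,
                "x": spont_cols % X,
                "onset_s": spont_onsets,
                "amplitude": spont_amps,
            }
        ),
    )
    return stack, truth


def stim_vector_from_protocol(
    protocol: Protocol, n_stacks: int, stack_period_s: float, mode: str = "binary"
) -> StimVector:
    """Per-stack stimulus vector: episode at time t lands in stack
    floor(t / period) (current-stack assignment)."""
    counts = np.zeros(n_stacks, dtype=np.int64)
    for t_ev, n_pulses in zip(protocol.event_times_s, protocol.pulses_per_event):
        idx = int(t_ev / stack_period_s)
        if idx >= n_stacks:
            raise DurationError(f"episode at {t_ev}s beyond {n_stacks} stacks")
        counts[idx] += n_pulses if mode == "count" else 1
    if mode == "binary":
        return StimVector((counts > 0).astype(np.int64), mode="binary")
    return StimVector(counts, mode="count")


# ---------------------------------------------------------------------------
# sync-trace rendering
# ---------------------------------------------------------------------------

def simulate_sync(
    protocol: Protocol,
    geom: AcquisitionGeometry,
    fs_hz: float = 1000.0,
    duration_s: float | None = None,
    stack_period_s: float = 0.5,
    galvo_amplitude_v: float = 5.0,
    galvo_noise_sd_v: float = 0.002,
    ttl_noise_sd_v: float = 0.005,
    seed: int = 0,
) -> SyncRecording:
    """Render the dual-channel state recording matching a protocol.

    The galvo channel is one sawtooth ramp per frame (frame period =
    stack_period / frames_per_stack) with an instantaneous flyback; the
    TTL channel is baseline noise plus one 2-3-sample pulse per delivered
    pulse with peak amplitudes drawn uniformly in [0.1, 2] V (the
    sub-sampled appearance of 5 V stimulator pulses at 1 kHz).
    """
    if duration_s is None:
        duration_s = protocol.duration_s + 2.0 * stack_period_s
    if duration_s < protocol.duration_s:
        raise DurationError(
            f"duration {duration_s}s does not cover protocol ({protocol.duration_s}s)"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    frame_period = stack_period_s / geom.frames_per_stack * fs_hz  # samples, float
    if frame_period < 2:
        raise ParameterError("frame period below 2 samples; raise fs or slow the scan")
    i = np.arange(n)
    frame_idx = np.floor(i / frame_period)
    phase = (i - frame_idx * frame_period) / frame_period
    galvo = galvo_amplitude_v * phase
    if galvo_noise_sd_v > 0:
        galvo = galvo + rng.standard_normal(n) * galvo_noise_sd_v

    ttl = rng.standard_normal(n) * ttl_noise_sd_v if ttl_noise_sd_v > 0 else np.zeros(n)
    for t_pulse in protocol.pulse_times_s():
        s = int(round(t_pulse * fs_hz))
        if s >= n:
            continue
        amp = rng.uniform(0.1, 2.0)
        width3 = rng.random() < 0.5
        ttl[s] += amp
        if s + 1 < n:
            ttl[s + 1] += 0.55 * amp
        if width3 and s - 1 >= 0:
            ttl[s - 1] += 0.45 * amp
    return SyncRecording(galvo_y=galvo, stim_ttl=ttl, fs_hz=fs_hz)


def sync_ground_truth(
    protocol: Protocol,
    geom: AcquisitionGeometry,
    fs_hz: float = 1000.0,
    stack_period_s: float = 0.5,
) -> list[tuple[int, int]]:
    """Exact (t, z) of every protocol pulse under the rendered frame grid."""
    frame_period = stack_period_s / geom.frames_per_stack * fs_hz
    out = []
    for t_pulse in protocol.pulse_times_s():
        s = int(round(t_pulse * fs_hz))
        f = int(math.floor(s / frame_period + 1e-9))
        B = geom.frames_per_stack
        within = f % B
        z = within if within < geom.planes_per_stack else -1
        out.append((f // B, z))
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_detection(
    detected, truth: GroundTruth, threshold: float | None = None
) -> tuple[float, float, float]:
    """(sensitivity, false-positive rate, detected fraction) of a detection.

    ``detected`` is a CorrelationMap (scored as values > threshold within
    its mask), a boolean (z, y, x) volume, or a list of (z, y, x) voxels.
    """
    if not truth.responder_voxels:
        raise TruthError("ground truth contains no responder voxels")
    shape = truth.responder_mask.shape
    det = np.zeros(shape, dtype=bool)
    analysis = np.ones(shape, dtype=bool)
    if hasattr(detected, "values") and hasattr(detected, "params"):
        if threshold is None:
            raise ParameterError("threshold required when scoring a CorrelationMap")
        det = detected.values > threshold
        if detected.mask is not None:
            analysis = np.asarray(detected.mask, dtype=bool)
            det &= analysis
    elif isinstance(detected, np.ndarray) and detected.dtype == bool:
        if detected.shape != shape:
            raise ParameterError(f"mask shape {detected.shape} != truth shape {shape}")
        det = detected
    else:
        for z, y, x in detected:
            det[int(z), int(y), int(x)] = True
    resp = truth.responder_mask & analysis
    non_resp = ~truth.responder_mask & analysis
    if resp.sum() == 0:
        raise TruthError("no responder voxels inside the analysis mask")
    sensitivity = float((det & resp).sum() / resp.sum())
    fpr = float((det & non_resp).sum() / non_resp.sum()) if non_resp.sum() else 0.0
    fraction = float(det.sum() / analysis.sum())
    return sensitivity, fpr, fraction
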