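# Methods

`voxcorr` analyzes 5D (x, y, z, t, channel) two-photon Ca²⁺ imaging of
astrocytes for responses that are time-locked to sparse electrical
stimulation of nearby axons. Astrocytic Ca²⁺ activity is dominated by
spontaneous transients in the fine-process meshwork (gliapil), the evoked
responses are small, spatially unpredictable, and jittered in delay, so
the package deliberately avoids ROI segmentation and instead screens every
voxel with a lagged-correlation statistic calibrated against a permutation
null. This note records the models, the defaults and why they were
chosen, and what the synthetic benchmark does and does not demonstrate.

## Data model

A hyperstack is a dense array in canonical axis order `(c, t, z, y, x)`
with voxel size (µm), stack period (seconds per complete z-stack volume),
and channel labels. On disk the ImageJ hyperstack TIFF dialect is used:
one 2D page per (c, z, t), interleaved channel-fastest
(`p = t·Z·C + z·C + c`), dimensions in the ImageJ
`channels/slices/frames` metadata, calibration in the resolution tags
plus `spacing`/`finterval`. Supported voxel types are uint8, uint16 and
float32; all arithmetic promotes to float32 or float64. Whole-file
in-memory loading is assumed (no memory mapping); files produced by
bidirectional z-scanning are assumed to store planes in monotonic z
order per stack.

## 5D Gaussian filtering

Smoothing is a separable sequence of 1D Gaussian convolutions over any
subset of {x, y, z, t}; the channel axis is never filtered. Kernels are
truncated at radius ⌈4σ⌉ and renormalized to unit sum, so constants are
preserved to float rounding. The default boundary is `mirror`
(reflection about the edge sample without duplicating it); `reflect`,
`nearest`, `wrap` and `constant` are available. The DC-offset option
zeroes voxels *strictly below* a threshold — a noise-floor blanking for
low-level electrical pickup, not a baseline subtraction — and runs
before smoothing, because blanking afterwards would re-introduce
sub-threshold values at transient edges.

## ROI traces and activity masks

ROIs (rectangle, ellipse, polygon, mask) rasterize by the pixel-center
rule and are pinned to a plane or averaged over z; both modes are
offered because a 2D ROI on a volume is ambiguous. Trace sample *i*
carries the start time of stack *i* (`i · stack_period_s`). Min/max
normalization maps a trace onto [0, 1] and rejects constant traces;
running averages use a centered window that shrinks at the edges.
External stimulus/ephys traces (1- or 2-column ASCII) are resampled onto
the stack time base: two-level (TTL-like) traces become per-stack
indicators (1 iff any sample in the stack interval exceeds half the
trace maximum), anything else becomes per-interval means. The
SD-threshold activity mask averages a short time window (e.g. 2 s) into
one volume and marks voxels above the volume mean + k·SD (k = 4
typical); it is a display/masking aid, not a detector.

## Voxel-wise normalized cumulative cross-correlation

For channel c, every voxel trace F is optionally pre-averaged over an
in-plane (2m+1)² neighborhood (shrunk at borders), normalized, and
correlated against a per-stack stimulus vector s at lags k = 0…K, with
positive lag meaning fluorescence follows stimulus:

    r_k = Pearson( s[0:T−k], F[k:T] )
    cumulative:  R = Σ_{k=0}^{K} r_k          (|R| ≤ K+1)
    peak:        R = max_k r_k, with argmax   (|R| ≤ 1, ties → smallest k)

The cumulative form is the workhorse: when the response delay jitters
from trial to trial by up to ~K/2 frames, the response mass lands at
different lags in different trials, and summing the whole lag window
keeps it, whereas any single fixed lag loses most trials. K is set in
frames (a seconds flag converts via the stack period); windows
equivalent to 2.5–5 s are typical at ~2 Hz stack rates, and K must
leave at least 8 overlapping samples (`K ≤ T − 8`).

Normalization default is a running-percentile ΔF/F₀: F₀[i] is the 10th
percentile of frames [i−w, i+w] (edge-shrunk) and the output is
(F−F₀)/max(F₀, ε) with ε = 10⁻⁶ × the global mean. The half-width w
defaults to K, so the baseline estimate always draws on a full
correlation window on either side of i; a shorter window lets F₀ ride
up on the response itself and cancels a large part of the statistic.
Global z-scoring and no normalization are also available (Pearson is
invariant to per-voxel affine maps, so these differ from ΔF/F₀ only
through the time-dependence of F₀). Zero-variance traces or overlaps
yield r = 0 with a degenerate flag — never NaN — so maps stay finite.

**Significance.** The null preserves the stimulus autocorrelation by
circularly shifting s by offsets drawn uniformly from [K+1, T−K−1]; each
of `n_null` (default 200) shifts is scored on a random subsample of
in-mask voxels (default 2000), and the pooled `null_percentile` (default
99.9) becomes the detection threshold. Per-voxel p-values are pooled
exceedance fractions; an optional Benjamini–Hochberg correction is *not*
applied by default since the quantity of interest is the responding
volume fraction, i.e. the fraction of in-mask voxels whose statistic
exceeds the threshold. Identical seeds give identical thresholds, and
results are independent of any execution partitioning (the map is a pure
per-voxel function).

## Synchronization

Acquisition timing is reconstructed from a dual-channel 1 kHz state
recording: the Y-galvanometer feedback (one sawtooth ramp per frame
scan) and a split-off of the stimulator TTL. Frame boundaries are
negative-going excursions of the galvo first-difference exceeding
8 × MAD (falling back to half the deepest excursion when the MAD
vanishes on noiseless ramps), merged over consecutive samples, with a
refractory period; the frame start is the sample after the flyback, and
a start at index 0 is prepended when the recording opens mid-ramp.

TTL pulses after heavy sub-sampling last 2–3 samples with amplitudes
anywhere in ~0.1–2 V, so detection takes local maxima above the channel
*median* + 0.05 V (≈10× the baseline noise SD) — baseline-relative, so
a DC offset on the channel is irrelevant, and deliberately below the
smallest expected pulse amplitude. Each event sample maps to frame
index f (count of frame starts ≤ sample, −1), stack t = f div B and
plane z = f mod B for a per-stack budget B = planes + overhead frames;
events in overhead frames keep t with z = −1 and still enter the
stimulus vector (the stimulus time matters even when no plane was
imaging). The within-frame line estimate y is linear in elapsed samples
and approximate by construction. A stimulus mid-stack is assigned to the
*current* stack index (convention).

## Synthetic benchmark

The generator renders the regime the detector is built for. Defaults
(one channel, 600 stacks of 8×32×32 voxels at 0.5 s/stack, i.e. 5 min at
2 Hz volume rate):

| parameter | default | meaning |
|---|---|---|
| baseline F₀ | 100 a.u. | resting fluorescence |
| noise SD | 10 a.u. | additive Gaussian per voxel-frame (10% of F₀) |
| spontaneous rate | 6 events / voxel·hour | Poisson-timed endogenous transients everywhere |
| transient kinetics | τ_rise 0.2 s, τ_decay 2.0 s | double-exponential (1−e^(−t/τr))·e^(−t/τd), unit-peak scaled |
| responder blob | 0.5% of volume (contiguous, ~41 voxels) | the reliably responding compartment |
| response probability | 0.8 per trial | trial-to-trial failures |
| delay jitter | uniform 0–2.5 s (= K/2 frames at K=10) | variable stimulus-to-response latency |
| evoked amplitude | 3 × noise SD | single-voxel SNR 3 at the transient peak |

The kinetics deserve a note: neuronal GCaMP6f decays in a few hundred
milliseconds, but astrocytic microdomain transients last seconds, and a
detector configured with 2.5–5 s lag windows presupposes responses on
that time scale. At a 0.5 s stack period, sub-second decay would leave
1–2 samples per transient and make amplitude-3σ responses essentially
undetectable by any lag-window statistic; τ_decay = 2 s gives ~4–6
samples per transient, which matches what volumetric astrocyte recordings
show. Spontaneous and evoked transients share kinetics.

The benchmark protocol is the sparse-stimulation paradigm — three epochs
of five single-pulse episodes at 0.05 Hz separated by ~2 min quiescent
gaps, 15 episodes in ~9 min — run in its 2×-sped-up variant (0.1 Hz,
60 s gaps, 15 episodes in ~4.5 min) so it fits the 5 min default
acquisition. A graded-train protocol (episodes of 1, 2, 3, 4, 5, 1, 2
pulses at 100 Hz, every 10 s) is also provided for train-response
studies. Matching galvo/TTL recordings are rendered with per-frame
sawtooth ramps and 2–3-sample TTL pulses of 0.1–2 V.

With these defaults and a cumulative K = 10 (5 s) detector at the
99.9th-percentile shift-null threshold, the measured operating point is
sensitivity ≈ 0.93–1.0, false-positive rate ≈ 0.07–0.14%, estimated
responding fraction ≈ 0.5–0.65% against the planted 0.5% (seeds 1–42);
a fixed-lag (k = 0 only) detector on the same data recovers essentially
nothing, because only ~1 trial in 5 has a delay under one frame. The XY
pre-averaging radius is 0 in this benchmark: scoring is voxel-level, and
a 3×3 average would smear signal into the ~90-voxel shell around the
blob, which the truth tables count as false positives.

**What the benchmark does not show.** The generator has no optical PSF,
no motion, no bleaching, no realistic astrocyte morphology, and its
noise is Gaussian (an optional variance∝signal term approximates photon
statistics but is off by default). Passing it demonstrates the
statistical machinery — calibration of the null, jitter tolerance of the
cumulative statistic, exactness of the sync arithmetic — not performance
on any particular microscope's data.

## Numerical choices and degenerate inputs

- Minimum Pearson overlap 8 samples; shorter overlaps are lag errors.
- Peak-mode ties break toward the smallest lag; r values are clipped to
  [−1, 1] against float drift.
- Degenerate traces/overlaps/stimuli give 0 with flags, not exceptions;
  an all-zero stimulus flags the whole map degenerate.
- The running percentile uses linear interpolation (numpy default).
- Filtering arithmetic is float32 end-to-end; correlation arithmetic is
  float64.
- Circular-shift offsets exclude [−K, K] so no null draw is
  lag-adjacent to the true alignment; `n_null = 1` is allowed and gives
  the (degenerate but defined) percentile of a single shift's values.

## Problem sizes

The shipped tests and the acceptance script run the full benchmark at
the default (1, 600, 8, 32, 32) size — 8192 voxels, 11 lags, 200 null
shifts — which completes in well under a minute per run on one CPU;
oracle checks use 20 random stacks up to (2, 7, 5, 9, 9) against a
dense-convolution reference and 200 random trace/stimulus/lag triples
against a per-lag Pearson loop. These sizes were chosen as the smallest
that exercise every code path at meaningful statistical power (the
99.9th-percentile calibration needs thousands of voxels to be testable
at all).

## Known limitations

- No merging of suprathreshold voxels into functional domains: the
  output is deliberately a voxel list + volume fraction.
- ABF and other binary electrophysiology formats are not parsed; export
  to ASCII first.
- OME-TIFF, HDF5 and vendor formats are out of scope; so is lazy access
  for stacks larger than RAM.
- The y (line) coordinate of events is a linear estimate only; per-voxel
  x-y timing would need a pixel clock.
- The interactive, real-time displays of the original plugin workflow
  are replaced by batch CSV/PNG outputs.
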