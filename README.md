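# voxcorr

Scriptable analysis of 5D — x, y, z, time, channel — two-photon Ca²⁺
imaging, built for astrocytes.

Astrocytic Ca²⁺ activity does not behave like neuronal somatic firing:
most of it happens in the optically sub-resolved meshwork of fine
processes (the *gliapil*), transients lack stereotyped kinetics, and the
small compartments that reliably respond to sparse axonal stimulation sit
at unpredictable 3D locations, buried in abundant spontaneous activity
and jittered in their response delay. ROI- and matrix-factorization-based
pipelines built for neuronal somata break down here. `voxcorr` instead
works voxel-by-voxel over whole imaged volumes and answers the question
*which voxels follow the stimulus?* without segmenting anything.

The toolkit covers the full workflow around that question:

- **`voxcorr.hyperstack`** — read/write 5D stacks in the ImageJ
  hyperstack TIFF dialect (page order `p = t·Z·C + z·C + c`, metadata
  `channels/slices/frames`), canonical in-memory order `(c, t, z, y, x)`,
  cropping, plane addressing.
- **`voxcorr.filter5d`** — separable Gaussian smoothing over any of
  x, y, z, t (never across channels), kernels truncated at ⌈4σ⌉, plus a
  DC-offset option that blanks voxels below a noise floor.
- **`voxcorr.roi`** — multi-ROI trace extraction along t or z, min/max
  normalization, running-average overlays, external stimulus/ephys trace
  alignment, SD-threshold activity masks.
- **`voxcorr.sync`** — reconstruct frame timing from a 1 kHz
  Y-galvanometer feedback trace, detect stimulator TTL pulses (2–3
  samples, 0.1–2 V after sub-sampling), and map every stimulation event
  to its (stack t, plane z, ~line y) coordinate.
- **`voxcorr.xcorr`** — the detector: per-voxel *normalized cumulative
  cross-correlation* against a per-stack stimulus vector,

      r_k = Pearson(s[0:T−k], F[k:T]),   R = Σ_{k=0}^{K} r_k,

  with running-percentile ΔF/F₀ normalization, optional in-plane
  pre-averaging, a circular-shift permutation null for thresholding, and
  responding-volume quantification. A peak statistic
  (max_k r_k, with the lag of the peak) is also available; the cumulative
  form is what tolerates trial-to-trial delay jitter.
- **`voxcorr.synth`** — synthetic GCaMP6f-like stacks with planted
  ground truth (spontaneous transients everywhere, a small contiguous
  responder blob with per-trial failures and jittered delays), standard
  stimulation protocols (15 sparse episodes at 0.05 Hz in three epochs;
  graded 1,2,3,4,5,1,2-pulse trains), and matching galvo/TTL recordings.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

Simulate a 5-minute volumetric recording (600 stacks of 8×32×32 voxels
at 2 Hz volume rate) with a planted responder blob occupying 0.5% of the
volume, stimulated by 15 sparse episodes, then detect the responding
volume:

```sh
voxcorr simulate --preset sparse2x --out stack.tif \
    --truth-prefix truth --stim-out stim.txt --seed 1
voxcorr xcorr stack.tif --stim stim.txt --lag-seconds 5 \
    --mode cumulative --seed 1 --out-prefix resp
```

which logs

```
voxcorr INFO simulated stack.tif (15 episodes, 41 responder voxels)
voxcorr INFO map resp_map.tif: threshold=0.4280 responding fraction=0.5981% (49 voxels)
```

and writes the correlation map and p-map as float32 TIFF volumes, the
suprathreshold voxel list (`resp_voxels.csv`, sorted by statistic), and a
parameter echo. Reading the numbers: the 99.9th percentile of the
circular-shift null distribution puts the detection threshold at a
cumulative statistic of 0.428; 49 of 8192 voxels (0.60% of the analyzed
volume) exceed it, against a planted responding fraction of 0.50% —
the sub-1% responding-volume regime this analysis is designed to
quantify. The top entries of `resp_voxels.csv`,

```
z,y,x,statistic
4,15,17,1.0449
3,16,15,0.9683
5,17,17,0.9627
```

all lie inside the planted blob (centered at z=4, y=16, x=16; compare
`truth_responders.csv`). Every output carries a `.prov.json` sidecar with
parameters, seed and input checksums sufficient to re-run the command.

The same pipeline runs from Python:

```python
import voxcorr as vc

cfg = vc.default_config(seed=1)
proto = vc.make_sparse_protocol(rate_hz=0.1, gap_s=60.0)  # 2x-sped-up
stack, truth = vc.simulate_stack(cfg, proto)
stim = vc.stim_vector_from_protocol(proto, cfg.shape[1], cfg.stack_period_s)

params = vc.CorrelationParams(lag_window_frames=10, mode="cumulative", seed=1)
cmap = vc.correlation_map(stack, stim, 0, params)
null = vc.shift_null(stack, stim, 0, params, observed=cmap)
fraction, voxels = vc.responding_volume(cmap, null.threshold)
sens, fpr, _ = vc.score_detection(cmap, truth, null.threshold)
```

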