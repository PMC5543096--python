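# iosproc

Post-processing and denoising-technique benchmarking for multi-wavelength
**intrinsic optical signal (IOS) imaging** of the cortex.

IOS imaging records cortical reflectance under visible illumination;
stimulus-evoked haemodynamics change local HbO₂/HbR concentrations and
hence absorption. The raw recordings are dominated by breathing (~1.2 Hz)
and heartbeat (~6 Hz) interference, electrical camera noise, slow drift
and inter-trial variability, so the choice of signal-processing technique
decides whether the evoked response is visible at all. `iosproc` is for
researchers running (or simulating) interleaved multi-wavelength IOS
experiments who want a tested, reproducible implementation of the full
chain and a principled way to compare denoising strategies on their own
disturbance regime.

The package covers:

* **Demultiplexing** of frame-interleaved multi-wavelength stacks
  (60 fps camera cycling 470/530/588/627 nm → four 15 fps stacks),
  trial segmentation, cropping, TIFF + YAML-sidecar I/O.
* **Modified Beer–Lambert unmixing**: per pixel and frame,
  ΔA_λ = log₁₀(I₀/I_a) and the over-determined system
  ΔA = [ε·l](ΔC_O, ΔC_R)ᵀ solved by least squares; ΔC_T = ΔC_O + ΔC_R.
* **Seven denoising techniques** as sklearn-style transformers, each
  mapping an N-trial stack to a single-trial equivalent: trial averaging,
  Butterworth temporal low-pass (order 10, 0.5 Hz) and band-pass
  (order 20, 0.09–0.5 Hz), PCA reconstruction (top 25% of components),
  truncated difference (components correlated with the stimulus
  sequence), global signal regression, and spatial Gaussian smoothing
  (σ = 200 µm).
* **Response extraction**: 50 × 50 px ROI temporal traces and
  frames-41–70 spatial maps, with automated ROI placement.
* **Split-half SNR estimation** — P_noise = power(data1 − data2)/2,
  P_total = (power(data1) + power(data2))/2,
  SNR = (P_total − P_noise)/P_noise — and a full
  technique × trial-count benchmark over a synthetic cohort with paired
  statistics against averaging.
* **A synthetic-data generator** with known ground truth emulating the
  acquisition and its disturbance structure (see `docs/methods.md`), so
  every stage is testable without any download.

## Worked example

```python
import numpy as np
import iosproc as ip

# one synthetic session: 20 trials, 64x64 px covering a 5.2 mm field
acq  = ip.AcquisitionConfig(frame_shape=(64, 64), n_trials=20, pixel_pitch_um=81.25)
dist = ip.DisturbanceConfig()                      # breathing, heartbeat, drift, noise
resp = ip.ResponseConfig(spatial_sigma=8.0)        # 0.65 mm response blob
raw, truth = ip.generate_raw_stack(acq, dist, resp, seed=7, dtype=np.float32)

stacks   = ip.demultiplex(raw)                     # four 15 fps wavelength stacks
bandpass = ip.TemporalBandpass(frames_per_trial=acq.frames_per_trial)
unmixer  = ip.BeerLambertUnmixer(n_baseline_frames=acq.n_baseline_frames).fit(None)
haemo    = unmixer.transform([bandpass.transform(ws) for ws in stacks])

center = ip.locate_peak_roi(haemo, roi_size=12)
trace  = ip.temporal_response(haemo, center, roi_size=12)

# split-half SNR: first 10 vs last 10 trials
half   = acq.frames_per_trial * 10
traces = []
for sl in (slice(None, half), slice(half, None)):
    h = unmixer.transform([bandpass.transform(ws.data[:, :, sl]) for ws in stacks])
    traces.append(ip.temporal_response(h, center, roi_size=12).trace)
est = ip.snr_split_half(*traces)
```

Output:

```
raw stack: (64, 64, 12000) (4 wavelengths interleaved)
ROI centre: (32, 32) (true blob centre (32, 32))
HbT trace peak at frame 54 (3.60 s), amplitude 3.031e-07
split-half temporal SNR (bandpass, 10 trials/half): 12.1
```

The 12 000 interleaved frames demultiplex into four 3 000-frame stacks;
after band-pass filtering and unmixing, the automated ROI lands on the
true blob centre, the total-haemoglobin trace peaks ~2.1 s after stimulus
onset (within the frames-41–70 response window), and the split-half
estimate says the shared response carries ~12× the power of the
half-to-half noise. Relative concentration units are used throughout
(pathlengths default to 1).

A command-line interface mirrors the stages:

```bash
iosproc simulate  --config cfg.yaml --seed 1 --out sim/
iosproc demux     --in sim/raw.tiff --out demux/
iosproc process   --technique bandpass --in sim/raw.tiff --out proc/
iosproc benchmark --seed 1 --out bench/     # technique x trial-count SNR tables
iosproc spectrum  --in trace.csv --fs 15 --out spec.csv
```

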