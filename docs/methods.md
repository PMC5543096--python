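# Methods

## The processing chain

Intrinsic optical signal (IOS) imaging records cortical reflectance under
visible-light illumination; stimulus-evoked haemodynamics change local
haemoglobin concentrations and hence absorption. The package implements the
standard multi-spectral pipeline:

1. **Acquisition model.** The camera runs at 60 fps while an LED ring
   cycles four wavelengths (470, 530, 588, 627 nm), one per frame, so each
   wavelength is sampled at 15 fps. A trial is 10 s: 1.5 s baseline, 1.5 s
   stimulus, 7 s post-stimulus — 600 camera frames, 150 per wavelength.
2. **Demultiplexing** splits the interleaved stack positionally
   (frame index mod cycle length); it is pure indexing and exactly
   invertible.
3. **Denoising technique** (one of seven, below) maps the N-trial
   per-wavelength stack to a single-trial-equivalent stack.
4. **Modified Beer–Lambert unmixing.** Per pixel and frame,
   ΔA_λ = log₁₀(I₀/I_a) with I₀ the mean over the baseline window
   (frames 1–22, 1-based), and the over-determined 4×2 system
   ΔA = [ε·l]·(ΔC_O, ΔC_R)ᵀ is solved by least squares. ΔC_T = ΔC_O + ΔC_R.
   The textbook sign (log₁₀(I₀/I_a), positive ΔA for more absorber) is the
   default; the inverted ratio sometimes seen in print is available as
   `printed_sign=True`. Pathlengths default to 1, so concentrations are in
   relative units; absolute calibration is explicitly out of scope.
5. **Endpoints.** Temporal response: mean over a 50 × 50 px ROI centred on
   the peak response, one value per frame. Spatial response: mean over
   frames 41–70 (30 frames spanning the response peak). ROI placement is
   automated (argmax of the lightly smoothed windowed map over fully
   contained ROI positions, deterministic tie-break), since manual
   placement is not reproducible.

## The seven techniques

All run on raw per-wavelength intensity stacks before unmixing (an
optional mode applies them to concentration stacks instead), and all end
with trial averaging.

* **Averaging** — R(t) = (1/N) Σₙ Cₙ(t); the baseline everything else is
  compared against.
* **Temporal low-pass** — order-10 Butterworth, 0.5 Hz cutoff at 15 Hz
  sampling, applied to each pixel's continuous N-trial series. The cutoff
  sits just below the breathing/heartbeat band.
* **Temporal band-pass** — 0.09–0.5 Hz Butterworth of overall order 20
  (ten pole pairs — the convention in which a "20th-order bandpass" has 20
  poles); the low edge sits just below the 0.1 Hz stimulus fundamental, so
  offset and slow drift are removed too.
* **PCA** — SVD of the mean-subtracted pixels-by-time matrix; reconstruct
  from the top ⌈0.25·min(L, T)⌉ components (at least one). The fraction is
  a config parameter standing in for the scree-plot elbow.
* **Truncated difference** — same decomposition, but a component is kept
  when the absolute Pearson correlation between its temporal course and
  the trial-tiled stimulus presentation sequence w(t) (−1 on frames 1–22,
  +1 on frames 41–70, 0 elsewhere; only w ≠ 0 frames enter the
  correlation) exceeds 3× the mean correlation over all components.
* **Global signal regression** — per pixel, the least-squares projection
  onto the all-pixel mean time course is removed:
  βᵢ = (gᵀg)⁻¹gᵀCᵢ, Rᵢ = Cᵢ − g βᵢ.
* **Spatial Gaussian** — each frame convolved with a normalised 2-D
  Gaussian, σ = 200 µm converted through the pixel pitch (20 µm/px at full
  resolution → σ = 10 px), kernel truncated at 4σ and renormalised to unit
  sum, reflective boundaries — total intensity is conserved exactly.

Numerical choices:

* Filtering is zero-phase (forward–backward, `sosfiltfilt`) by default:
  the split-half comparison would otherwise be corrupted by group delay.
  The effective magnitude response is the square of the single-pass
  response; a causal single-pass mode exists. Edge transients at the
  recording boundaries are retained (the filter routine's default odd
  padding only) and simply dilute into the trial average.
* Band-pass and GSR remove the temporal mean, but the downstream
  absorbance ratio needs positive intensities, so the transformer stage
  restores each pixel's pre-processing temporal mean (PCA-family already
  re-adds the subtracted mean). The low-level `gsr` and `butter_filter`
  functions remain the unmodified textbook forms. GSR runs on
  mean-removed series (equivalent to including a constant regressor),
  which is the standard formulation when the raw series has a large DC
  component.
* PCA and truncated difference share one decomposition, computed through
  the Gram matrix on the smaller side of the pixels-by-time matrix
  (eigendecomposition of CCᵀ or CᵀC). Reconstruction is the orthogonal
  projection U_k U_kᵀ C, which is exact (machine precision) for full-rank
  selections and roughly an order of magnitude faster than a full SVD at
  benchmark sizes. Component signs are fixed deterministically; components
  below the decomposition's numerical noise floor
  (s ≤ s₀·√(eps·max(L,T))) are never selected by the correlation rule.
* Degenerate inputs fail loudly: non-divisible frame counts name the
  remainder, non-positive intensities refuse the logarithm, an empty
  truncated-difference selection suggests lowering the threshold, a flat
  spatial map tie-breaks the ROI to scan order.

## Split-half SNR

True single-trial IOS responses are unknown, so signal and noise are
estimated from two equal session halves processed identically: shared
structure counts as signal, the half-difference as noise.

    power(R)  = Σ |R(z)|²
    P_noise   = power(data1 − data2)/2
    P_total   = (power(data1) + power(data2))/2
    SNR       = (P_total − P_noise)/P_noise

The estimator assumes zero-mean additive noise independent between halves.
Negative estimates (P_noise > P_total, possible at very low SNR) are
reported as computed with a flag, never clamped. Monte-Carlo calibration
(tests) shows the median estimate over 200 draws recovers true ratios of
0.5–10 within 10%. Both halves share one ROI, located on the combined
session, so placement disagreement cannot masquerade as noise. SNR is
reported as the raw ratio (a dB view is a trivial transform the reader can
apply).

## The synthetic-data generator

No recordings are deposited with the study, so every quantitative claim is
exercised on synthetic sessions with known ground truth. The forward model
per wavelength is

    I(x,y,t) = I₀(λ) · 10^(−ΔA(x,y,t,λ)) · (1 + d(t)) + η,
    ΔA = ε_O l_O ΔC_O + ε_R l_R ΔC_R,

using the same extinction/pathlength table as the unmixer, so the
noise-free round trip is exact (verified to <10⁻⁸ relative, observed
~10⁻¹⁴). Concentration fields are held constant within each 4-frame
wavelength cycle — the same simultaneity assumption the unmixing makes —
while disturbances and noise vary at the full 60 fps.

**Response.** An isotropic Gaussian blob (σ = 0.65 mm) times a causal
gamma-variate kernel: zero before onset (1.5 s into the trial), unit peak
2.0 s after onset (frame ~52, inside the 41–70 window), asymptotic decay
constant 1.2 s. Peak concentration changes default to ΔHbO₂ = +6·10⁻⁷ and
ΔHbR = −2·10⁻⁷ (relative molar units): at 530 nm this is a ~1.6% intensity
dip, a typical evoked IOS magnitude, and the periodic-interference RMS in
the ROI is ≥2× the response RMS, so a single trial shows no obvious
response — the regime the comparison is about. The amplitudes and blob
size also keep the response's singular value above the white-noise
singular-value bulk of the pixels-by-time matrix; below that edge no
component-selection scheme can isolate the response even in principle, and
the PCA-family techniques would degenerate rather than tie averaging.

**Disturbances.** Global multiplicative modulations, consistent with
breathing and heartbeat being spatially global (the premise that makes GSR
meaningful): sinusoids at 1.2 Hz (breathing, 2% amplitude) and 6 Hz
(heartbeat, 1%), each with two harmonics at successively halved amplitude;
harmonics above the per-wavelength Nyquist alias exactly as they would in
a real interleaved acquisition. The instantaneous phase of each source
performs a random walk (0.6 rad/√s), giving ~6 s phase coherence: a
1.2 Hz oscillator at 12 cycles per trial with a few-percent rate wander
accumulates radians of phase error per trial, so real periodic
interference is not locked to the trial clock. This matters structurally —
a perfectly periodic 1.2 Hz interferer has exactly 12 cycles per 10-s
trial, would survive trial averaging untouched, and would be counted as
*signal* by the split-half estimator. The spectral linewidth this induces
(~0.06 Hz) leaves the 1.2/6 Hz lines sharply detectable. Baseline drift is
a Gaussian random walk (increment SD 5·10⁻⁴/√s of relative intensity,
~2% wander over a 500 s session): a *deterministic* ramp would be
identical in both halves and read as signal, and a drift the band-pass
filter can remove while the low-pass cannot is precisely the reported
distinction between those two techniques. Electrical noise is i.i.d.
additive Gaussian per pixel per frame (SD 20 counts against ~1000-count
illumination, ~2%): large enough that spatial maps carry visible pixel
noise (what spatial smoothing removes), small enough that a 50 × 50 ROI
average suppresses it far below the biological disturbances, matching the
blank-versus-cortex quantification. Response amplitude jitters per trial
(lognormal-ish, SD 10%).

All randomness flows from one seed through `numpy.random.SeedSequence`
spawns per component, so each component is independently reproducible and
identical seeds give bit-identical stacks.

**What the generator does not emulate.** Optics (scattering, photon
transport), vascular architecture, motion/registration artefacts,
spatially structured biological noise, and any nonlinearity of the real
haemodynamic response. Passing benchmarks therefore demonstrate that the
pipeline and estimator behave correctly under the stated disturbance
structure — not that the technique ordering would be identical on any
particular real recording.

## Benchmark conditions and problem sizes

The cohort benchmark mirrors the study design: 19 synthetic animals, one
continuous session of 100 trials each, split into two 50-trial halves,
techniques applied to the first N ∈ {1, 10, 25, 50} trials of each half,
both endpoints scored per technique × N, means ± standard errors across
replicates, and paired t-tests against averaging. Each replicate draws its
own seed stream and mildly jittered disturbance amplitudes (lognormal,
SD 0.15), so cross-replicate dispersion is meaningful.

Benchmarks run at 32 × 32 pixels with the pixel pitch scaled to preserve
the field of view (162.5 µm/px), so the response blob (0.65 mm), smoothing
σ (200 µm) and ROI (1 mm) keep their physical sizes; trial structure,
rates and disturbance parameters are untouched. The packaged test suite
evaluates the seven-technique comparison at the 50-trial point and the
averaging trial-count curve at all four N. Spectral checks use 80 × 80 or
smaller frames: the disturbances are global, so ROI-mean spectra are
insensitive to frame size.

One measurement convention: on a 500 s concatenated record the sub-0.02 Hz
bins hold the random-walk baseline wander, so "the response peak below
0.3 Hz excluding DC" is searched in (0.02, 0.3] Hz. (Spectra in the
original protocol were computed on 10 s windows, whose fundamental is
0.1 Hz — slower content was never representable.)

## Known limitations

* Concentrations are relative (pathlength 1) by design; supplying a
  per-wavelength pathlength table is supported but uncalibrated.
* The Gram-matrix decomposition loses accuracy for singular values below
  ~√eps of the largest; irrelevant for denoising (such components are
  noise-floor by construction) but not suitable for precision spectral
  analysis of near-singular matrices.
* The split-half estimator counts any structure common to both halves as
  signal — including residual trial-locked interference; this is a
  property of the estimator itself, shared with the original design.
* GSR annihilates any signal that is itself global; it is meaningful only
  when disturbances dominate the global mean, which the generator's
  default regime guarantees.
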