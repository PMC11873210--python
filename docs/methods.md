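# Methods

This note documents the model implemented in `hearloc`, the choices made
where the underlying publications leave details open, and what the
synthetic fixtures do and do not establish.

## The ideal-observer model

Sound localization is treated as decoding: direction-dependent filtering
by head and ears (the HRTF) endows the acoustic input with cues, and an
ideal observer inverts this encoding optimally given its prior knowledge.
The acoustic input is

    X = [X_ITD, X^l, X^r],

the ITD together with the left/right-ear log-magnitude spectra sampled at
ERB-spaced centre frequencies. The posterior over direction is

    P(θ|X) ∝ P(X|θ) P(θ),     P(X|θ) = N(T(θ), Σ),

with a uniform spatial prior P(θ). The Gaussian form rests on two
transformations that make the measurement noise input-independent:
spectral magnitudes are expressed in dB, and the ITD is passed through a
nonlinear map into just-noticeable-difference (jnd) units. Under these
coordinates a single covariance Σ serves all directions and inputs, so the
decoder factors Σ once (Cholesky) and evaluates the whole grid per trial
with one triangular solve; batched decoding uses the expanded Mahalanobis
form `xWx − 2xWT + TWT` and a single matrix product per batch.

Σ is the sum of two parts:

* **measurement noise** — diagonal in the raw coordinates, default 1 jnd
  for the ITD and 1 dB per channel per ear, propagated through the feature
  map A as A·Σ_noise·Aᵀ. The defaults are round numbers in jnd-style
  units; psychoacoustic discrimination data can be substituted via
  `NoiseModel` (a per-channel vector is accepted).
* **source uncertainty** — the prior covariance Σ_S of the unknown source
  spectrum, injected identically into both ears (J = A·[0; I; I]) as
  J·Σ_S·Jᵀ. For the ISD representation, and for the ILD coordinate of the
  gradient representations, J vanishes identically: those features are
  source-invariant by construction.

The template T(θ) is the feature-map image of
`[itd_jnd(θ), H^l(θ) + mean_S, H^r(θ) + mean_S]`: directional filtering
plus the most likely source spectrum.

## Feature representations

All representations are explicit linear maps on the stacked raw vector
(length 2N+1, N = 30 channels), so covariances propagate exactly:

| tag | features | dim |
|---|---|---|
| `LOGMAG` | ITD, both ear spectra | 2N+1 |
| `ISD` | ITD, left−right spectrum | N+1 |
| `BIN_SG` | ITD, broadband ILD, both ears' spectral gradients | 2N |
| `POS_SG` | as BIN_SG, gradients half-wave rectified | 2N |
| `IPSI_SG` | as BIN_SG, contralateral gradient dropped at decode | N+1 |

The spectral gradient (SG) is the first difference across neighbouring
ERB channels (dB per channel step). Since the overall level carries no
directional information, `[level, ILD, dX^l, dX^r]` is an invertible
recombination of the two ear spectra, and LOGMAG and BIN_SG observers are
information-equivalent in the limit of large common-level variance in the
prior (verified as a property test: ≥ 99% MAP agreement).

Two representations involve a nonlinearity with no exact Gaussian
treatment:

* **POS_SG** — rectification destroys Gaussianity and no closed form for
  the resulting likelihood exists. We rectify both the observation and the
  templates and keep the BIN_SG covariance unchanged. This is one
  consistent reading; it preserves the information loss that motivates the
  representation (all-negative gradients become indistinguishable).
* **IPSI_SG** — the decoder conditions on the sign of the measured ITD
  (ties resolve to the left ear; a measure-zero event under continuous
  noise) and evaluates a reduced Gaussian in which the contralateral SG
  rows/columns of templates and Σ are dropped. The ITD/ILD cross-terms are
  retained, so ITD and ILD stay truly binaural cues.

## The ITD→jnd map

The exact nonlinear transform belongs to psychoacoustic discrimination
data not shipped here. The default is a tabulated odd, monotone
piecewise-linear curve: 1 jnd = 20 µs near zero, widening linearly from
100 µs to 1 jnd = 60 µs at |ITD| = 600 µs, constant beyond. Any tabulated
(ITD, jnd) curve can be supplied to `ItdJndMap`, so an empirically
calibrated transform drops in without code changes.

## Source priors

`build_prior` pools 0.2-s frames of corpus audio: each WAV file is
resampled to 44.1 kHz, chopped into non-overlapping frames (trailing
remainder discarded, frames below −60 dBFS RMS discarded as silence), and
reduced to 30 channel log-magnitudes by integrating a Hann-windowed
periodogram over 1-ERB-wide bands (a rectangular band; gammatone-shaped
weighting was considered and left out — at 1-ERB resolution the
difference is far below the corpus variance). Frame levels are *not*
normalized before pooling: the large common-level variance is part of the
statistics of real sound ensembles. The covariance uses the unbiased
(n−1) normalization; eigenvalues below −1e−8·trace are clipped to zero
with a logged warning.

The SG-domain prior is the exact pushforward through the first-difference
matrix D: mean D·m, covariance D·C·Dᵀ. Since D·1 = 0, any common-level
component vanishes — the reason SG priors estimated from very different
corpora look alike.

The **narrow prior** (mean = a reference spectrum, covariance = σ²I)
models an observer who effectively knows the stimulus; σ = 0 is the
known-spectrum limit.

## Synthetic fixtures

The package is benchmarked without downloads using two generators whose
defaults define the study conditions; they were chosen once, from the
structure real data exhibits, and are not tuned per experiment.

**Synthetic corpus** (`synth_corpus`): Gaussian frames with a mean falling
linearly by 30 dB across the band (the decrease observed for environmental
sound corpora), a common-level variance of 150 dB² (sounds differ mostly
in overall level), and per-channel fluctuations of std 9.5 dB with
exponentially decaying inter-channel correlation (length 2 ERB). These
values give an SG-domain std of ≈ 8.4 dB/ERB, in the regime corpus
estimates land in. What it does not emulate: non-Gaussian tails,
class-dependent spectral shapes, and temporal correlation between frames —
so tests establish estimator correctness and decoder behaviour under the
stated covariance structure, not corpus-specific numbers.

**Synthetic HRTFs** (`synth_hrtf`): a spherical-head (Woodworth) ITD,
`(a/c)(sinθ + θ)` with head radius 8.75 cm; a head-shadow ILD growing
linearly with normalized ERB frequency up to ±20 dB at |lateral| = 90°;
and a pinna-like Gaussian notch (depth 15 dB, width 0.8 ERB) whose centre
moves monotonically from 4 to 11 kHz as the polar angle sweeps its range,
making every grid direction's template distinct. A lateral-dependent
asymmetry (±35%) between the two ears' notch depths gives the interaural
spectral difference a weak polar cue, as pinna asymmetries do in real
heads; with the default noise this places the ISD observer's polar error
rate near 0.2, the regime reported for measured HRTFs. Per-subject
individuality comes from seeded jitter of head radius (±5%) and notch
mapping (±0.5 ERB). Not emulated: multiple notches/peaks, torso
reflections, frequency-dependent ITD.

## Coordinates, grids and metrics

Interaural-polar convention: lateral = angle from the midsagittal plane
(positive toward the left ear), polar ∈ [−90°, 270°) = position on the
cone of confusion (0 front, 90 up, 180 rear). The head frame is +x front,
+y left, +z up; SOFA spherical coordinates (azimuth CCW from front)
convert directly.

The benchmark grid is 2000 directions distributed uniformly over the
sphere (deterministic Fibonacci lattice by default; seeded i.i.d. uniform
optional), cut at elevation −45° (where HRTF measurements typically stop),
retaining ≈ (1+sin 45°)/2 ≈ 85.4% ≈ 1707 directions. The evaluation
region — within 30° of the midsagittal plane and 60° above/below the
horizontal plane in both front and rear hemifields — is implemented as
|lateral| ≤ 30° and polar ∈ [−60°, 60°] ∪ [120°, 240°], giving 599
directions on that grid; an elevation-band variant is available by
configuration.

Polar error rate: proportion of trials whose wrapped polar-angle error
exceeds 45°. The original benchmark's definition carries additional
subtleties around large lateral errors; an optional variant excludes
trials with lateral error > 45° from the denominator, the default counts
all trials. Great-circle error is arccos of the dot product of the unit
vectors.

## Monte-Carlo protocol

Per condition, every region direction is presented once per subject with a
fresh noise realization drawn from the *measurement* part of Σ only — the
source-uncertainty part describes the decoder's beliefs, not the world,
and the stimulus spectrum is applied explicitly. Responses are MAP
estimates over the full retained grid. Error rates pool all subjects'
trials into a single value; per-subject tables are also returned. One
master seed drives per-trial seeds through a splittable generator, so runs
are reproducible end to end. At the full trial count (20 subjects × 599
directions) the run-to-run relative std of the pooled rate is below 2%,
as expected from binomial scaling, so single-run rates are reported
without error bars.

Default problem sizes (20 000 corpus frames for the shipped priors, 5–20
synthetic subjects, the 2000-direction grid) keep a complete benchmark run
in the tens of seconds while leaving binomial noise well below the effect
sizes of interest; all sizes are plain function arguments.

## SOFA I/O and resampling

The reader accepts `SimpleFreeFieldHRIR` files (netCDF-4, hence readable
as HDF5), reduces each impulse response to channel log-magnitudes with a
rectangular-window periodogram (HRIRs are short deterministic filters;
windowing would only bias the band powers), and takes the ITD from
`Data.Delay` when it carries distinct per-ear delays, otherwise from
10%-of-peak onset crossings (sub-sample interpolated; cross-correlation
optional). The writer synthesizes zero-phase IRs whose piecewise-constant
power spectrum matches the channel levels exactly and stores delays in
`Data.Delay`, so write→read round-trips the set to machine precision.

Spatial resampling fits real spherical harmonics (default order 15) per
channel by Tikhonov-regularized least squares (default λ = 1e−4); λ = 0
requests plain least squares and raises on rank-deficient geometries with
advice to regularize.

## Numerical details

* Channel log-magnitudes are clamped at −120 dB re full scale; silence
  never produces −inf.
* Σ gets a 1e−10·trace diagonal jitter only if Cholesky fails; logged.
* Posteriors are log-sum-exp normalized; MAP ties break to the lowest
  index (deterministic, relevant only for degenerate inputs).
* The filterbank places the first centre exactly at the lower band edge
  and steps in exact ERB units; 300 Hz – 12 kHz at 1 ERB gives 30
  channels.

## Known limitations

* Static listening only: no head movements or dynamic cues, no
  reverberation, no background noise floor; all channels are assumed well
  above threshold.
* The POS_SG likelihood is an approximation (rectified Gaussian treated
  by rectifying templates and observations); a moment-matched variant
  would change its error rates quantitatively.
* The default ITD→jnd curve and noise sigmas are stand-ins at plausible
  magnitudes, not fits to discrimination data; absolute error rates shift
  with them, the qualitative orderings reported by the tests do not.
* Reproducing published error-rate *curves* exactly requires the measured
  HRTF sets and audio corpora those studies used; the synthetic fixtures
  reproduce the configuration counts and the qualitative shapes
  (flat ISD curve; rise–peak–fall of BIN_SG vs ripple density;
  monotonicity in ripple depth).
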