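# Methods

`tapkin` re-implements, as a tested library, a kinematic analysis of
automatic four-finger sequential tapping recorded as 60 Hz video-derived
keypoint trajectories. Because the human recordings behind this kind of
study are rarely shareable, the package pairs the analysis with a synthetic
trajectory generator whose ground truth lets every stage be validated by
parameter recovery.

## Data model

A trial is a `(frames x 17 keypoints x 2)` coordinate array in image
convention (y grows downward) with beep-event frame indices. The marker
layout places 14 points on the four tapping fingers — index and middle
carry tip/DIP/PIP/MCP, ring and little carry tip/PIP/MCP — plus three
anchors on the static thumb. Only the vertical coordinate is analyzed;
fingers tap mainly vertically. Coherence and amplitude metrics use the four
fingertips; pattern decoding uses all 14 tapping-finger points (91
unordered pairs). Files are long-format CSV plus a JSON sidecar; float
round-trip is bit-exact.

## Preprocessing

Order: **segment → duration-normalize → smooth → de-outlier → temporal ROI.**

- *Segment*: keep frames `[initiation − 30, termination + 90]`.
- *Normalize*: Fourier resampling (interpft-style) of each trial to its
  duration class's nominal length (6.71 s / 11.14 s at 60 Hz).
- *Smooth*: centered 6-frame (100 ms) moving average; the window shrinks at
  the edges so constants are preserved exactly.
- *De-outlier*: a sample whose difference from the last **retained** sample
  is ≥ 100 px is flagged (so spike runs are fully flagged) and all flagged
  or missing samples are filled by piecewise-linear interpolation. This
  deliberately replaces the spring-mesh `inpaint_nans` scheme: linear
  filling is deterministic, order-independent and adequate for isolated
  spikes.
- *ROI*: frames `i` with `60 ≤ i ≤ round(duration·60)`, measured from the
  initiation beep — from 1 s after movement onset (startup is not yet
  automatic) to the termination-beep frame. This inclusive convention is
  the unique simple rule giving 344 frames for 6.71 s and 609 for 11.14 s
  trials.

Note that because smoothing precedes outlier replacement (the order the
original description lists), a single-frame spike has already been spread
into six sub-threshold samples by the time the 100 px rule runs; the
de-outlier stage therefore mainly protects against extreme spikes and raw
missing samples. The alternative order is one line to change but is not
the documented pipeline.

## Wavelet coherence engine

Morlet CWT (ω₀ = 6) on a 40-point log-spaced frequency grid; the default
span [0.5, 15] Hz brackets observed tapping rates (3.07–8.43 Hz) with
margin for the first harmonic and is fully configurable. The transform is
computed in the Fourier domain with zero padding to a power of two.

Squared coherence follows the standard smoothed-spectra estimator

    R²(t,s) = |S(W_xy/s)|² / ( S(|W_x|²/s) · S(|W_y|²/s) )

with `S` a Gaussian time smoothing of standard deviation equal to the
scale, followed by a boxcar over scales of 0.6 octave total width with
fractional end weights (the convention of the widely used MATLAB
wavelet-coherence toolbox). Identical positive weights on auto- and
cross-spectra keep R² in [0, 1]; self-coherence is exactly 1. The cone of
influence marks points closer to a record edge than the e-folding time
√2·s; COI-invalid points are excluded from every average. Monte-Carlo
significance testing is not implemented — none of the downstream metrics
uses it.

Numerical caveat: for a noiseless pure tone the auto-spectra at remote
scales underflow toward zero and coherence there is 0/0; any measured or
simulated series with broadband content (noise floor ≥ machine epsilon of
the signal) is well behaved.

## Tapping rate, band, amplitude

The participant's **tapping rate** is the argmax of the inter-trial
coherence spectrum: WTC between every two same-condition, same-duration
trials of each fingertip, averaged over COI-valid ROI points, pairs,
fingertips, durations and conditions (all conditions pooled). The
**frequency range of interest** is the FWHM interval around that peak with
linearly interpolated endpoints. **Amplitude** A is the mean over the ROI
of the Hilbert-envelope magnitude of the fingertip series band-passed to
that interval (4th-order Butterworth applied forward–backward; one filter
settling length `fs/f_low` is trimmed at each end before averaging — a
zero-phase deviation from a causal single-pass filter, chosen so the
envelope stays aligned with the ROI; a causal mode exists for comparison).
The **modulation index** is `I_A = A_attention/A_reference − 1`.

### Known estimator bias

The coherence-spectrum argmax is a *positively biased* estimator of the
oscillation rate under this pipeline, by roughly 0.1–0.3 octave (one to
two grid steps) at realistic noise levels. Two mechanisms, both verified
on synthetic data: (i) the 100 ms moving average attenuates the broadband
noise floor faster above the tapping rate than the Morlet response's upper
log-frequency tail decays, tilting the coherence SNR upward; (ii) the
symmetric boxcar scale smoothing smears the asymmetric (fat-above-peak)
profile upward. The bias is stable across sessions, so rate *stability*
comparisons (correlations across experiments ≥ 0.9) are unaffected, and
the FWHM band comfortably contains the true rate; but point recovery of a
known generator rate lands one to two grid steps high. The test suite
states the one-grid-step recovery property and reports its failure rather
than widening the tolerance; users needing unbiased rates should fit the
spectrum's peak with an asymmetry-aware model rather than take the argmax.

## Pattern decoding

Per trial, coherence of all 91 tapping-keypoint pairs at 40 frequencies
gives a `time × 3640` block; COI-invalid entries are imputed with the
per-frequency mean over valid times (keeps the matrix complete without
injecting condition information). Blocks are pooled over trials (condition
by condition, trial order preserved), reduced by PCA to 80 components
fitted once per participant on all conditions together (per-fold PCA is a
flag), and cut per condition into **six trial-disjoint contiguous
datasets**. Sliding windows (60 points, step 4) over each dataset's
condition block are the samples (`⌊(N−60)/4⌋+1` per block); windows never
span dataset boundaries. Six-fold cross-validation holds each dataset out
once; the classifier is an SVM with RBF kernel, γ = 0.014, C = 1,
one-vs-one voting. The result is a row-normalized 4×4 confusion matrix,
per-condition accuracies and their mean (chance 0.25).

Feature normalization matters more than any other choice here, and the
package deliberately does **not** z-score the window features. The PCA
scores carry the class signal in their *variance ordering*: informative
components have large variance, and raw Euclidean distances between
windows are therefore dominated by informative directions. Per-feature
standardization divides each component by its own (signal-driven) scale
and inflates thousands of near-noise dimensions to unit variance; in
controlled experiments with strongly contrasted synthetic conditions this
buried the class structure completely (cross-validated accuracy 0.22
standardized vs 0.89 raw on identical folds). Raw features are also what
a MATLAB `fitcsvm` call applies by default. Because the raw mean squared
inter-sample distance (~10⁴ in pixel-derived units) would drive the fixed
kernel `exp(−0.014·d²)` to numerical zero, a single global scalar per
fold — computed from training-fold variances only — rescales the samples
so that γ·d̄² = 2, the operating point the libsvm-style default
γ = 1/n_features is designed for. A scalar preserves every distance ratio,
so this sets the kernel's width without touching the geometry.

A diagnostic nearest-class-centroid readout (`classifier="centroid"`) is
provided alongside the SVM: it measures whether class-mean pattern
differences generalize across folds even when sample-level margins are
dominated by trial-specific variability, and was instrumental in isolating
the normalization effect above.

Cutting datasets at trial boundaries (rather than at exactly equal point
counts) matters: the coherence features are time-smoothed over seconds, so
every window of a trial carries a trial-wide signature. If one trial's
points straddle two datasets, that signature leaks across
cross-validation folds and pushes *null* decoding to ≈ 0.4. With
trial-disjoint datasets the null sits at chance (0.25 ± 0.03 across
simulated cohorts). Dataset sizes may therefore differ by up to one trial's
worth of points, and per-dataset sample counts are derived and logged, not
asserted.

## Statistics

One- and two-way repeated-measures ANOVAs use the classical
subject-blocked sum-of-squares decompositions with each effect tested
against its own subject-interaction error term; effect size is partial
eta squared. No sphericity correction is applied by default (matching the
uncorrected degrees of freedom the analyses report); Greenhouse–Geisser is
available behind a flag. Paired and one-sample t-tests report Cohen's d
computed from the difference scores; identical paired samples return
t = 0, p = 1 (any other zero-variance input is an error). Pearson
correlation uses the t-based p-value; one-tailed variants via a flag.
The implementations are vectorized over replicate axes, which is what
makes the 10,000-replicate type-I calibrations in the test suite cheap;
they are cross-checked against `pingouin` to machine precision.

## The synthetic generator

Each tapping finger's vertical trace is

    y(t) = baseline + gain · A_joint · mod(t) · w(2π∫f(t)dt + lag + θ(t)) + ε(t)

with `w` either a raised-cosine tap pulse (default; narrow down-stroke,
normalized to unit fundamental so band-passed amplitudes recover gains
exactly, and rich in harmonics so band selection is non-trivial) or a pure
sinusoid for analytic tests. Defaults and what they emulate:

| parameter | default | meaning |
|---|---|---|
| tapping rate | U(3.07, 8.43) Hz per participant | observed rate range |
| finger phase lags | −k·π/2 | sequential index→middle→ring→little order |
| base amplitude | 25 px (tip; DIP 0.75, PIP 0.50, MCP 0.28) | fingertip excursion on a 1920×1080 frame |
| condition gains | reference 1; attended finger 1.2; whole-sequence 1.10–1.15 (little largest); unattended little 0.95 | direction and size of the reported amplitude effects |
| phase jitter SD | 0.05 / 0.20 / 0.20 / 0.35 rad (OU, τ = 0.4 s) | reference tapping is most automatic; single-finger scrutiny is least |
| amplitude jitter CV | 0.2 (OU, τ = half a tap period) | per-tap vigor variability; the main source of realistic coherence falloff away from the rate |
| rate drift | 0.05 Hz·√s random walk | slow tempo wander |
| noise SD | 2 px white | pose-estimation error |
| outliers | 0.002/frame/keypoint, ±120–250 px | single-frame tracking glitches |
| trials | 7 per condition × duration | standard 56-trial session |

One root seed drives everything; trial k of a session uses
`SeedSequence([seed, k])`, so any single trial is reproducible in
isolation. The same unit-variance noise paths are drawn whatever the
jitter SDs are, so varying a jitter level against a fixed seed is a paired
comparison. The thumb anchors are static up to noise. An optional
inter-finger coupling coefficient (mechanical enslaving) ships at 0; an
optional per-condition phase-lag offset exists but is invisible to
coherence magnitudes (constant phase factors out) and thus feeds only the
exported phase maps.

What the generator does **not** emulate: impact transients at key contact,
horizontal kinematics, postural drift of the whole hand, tracking-error
autocorrelation, or the rich idiosyncratic per-state movement signatures
that make real attentional conditions decodable at the rates human studies
report. Consequently, with default (amplitude-and-jitter only) condition
effects the decoder performs near chance; demonstrating above-chance
decoding in tests uses conditions separated by *fast* temporal-precision
differences (jitter τ = 0.15 s with SD spread 0.05–0.6 rad). Passing tests
therefore show the pipeline's correctness and sensitivity, not that every
real-world effect size is recoverable.

## Problem sizes used in tests

Recovery tests run at desk scale: sessions of 4–5 trials per condition
(short duration) for coherence/amplitude recovery, 20 seeds for
averaged-recovery claims, and 10 simulated participants × 8 trials per
condition (both durations) for the null-decoding calibration; statistical
calibrations use 10,000 vectorized replicates. These sizes give
Monte-Carlo errors comfortably inside the asserted tolerances.

## Repository shape

The package is a library: the public API plus `examples/` scripts are the
interface, and `run_pipeline` provides directory-level orchestration
(trajectory files in, delimited tables and JSON summaries out) for
scripted use. No console entry point is installed.
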