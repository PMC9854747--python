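# Methods

This note documents the models, parameter choices and numerical
decisions behind `fecgsqa`, and what the synthetic experiments do and do
not demonstrate.

## Problem setting

Abdominal (non-invasive) fetal ECG is a weak quasi-periodic fetal QRS
train superposed with a much stronger maternal ECG, baseline wander and
broadband noise from electrode motion and fetal movement. Fetal heart
rate (FHR) estimated from corrupted stretches is unreliable, so segments
are graded into three ordinal quality levels — high (essentially no
noise), medium (visible noise, amplitude well below the heartbeat) and
low (noise amplitude comparable to the heartbeat) — and the low-quality
segments are removed before FHR estimation. The classifier is
unsupervised: clustering structure plus a handful of labeled samples
(three per map neuron) replace a labeled training corpus.

## Synthetic data generator

`synthetic_fecg` emulates the study conditions: 60 s single-channel
recordings at 1 kHz, segmented into 3 s windows with 1.5 s overlap, and
a balanced evaluation set of 271 segments per quality level.

* **Fetal QRS**: Mexican-hat (Ricker) wavelets, σ = 7 ms (≈ 40 ms main
  lobe), unit peak amplitude, beat times at a configurable rate
  (drawn per recording from 110–160 bpm) with Gaussian RR jitter
  (sd 10 ms) and a floor of 25 % of the mean RR interval.
* **Maternal component**: same machinery at 60–100 bpm, σ = 14 ms,
  3× amplitude; **off by default**, emulating the signal after
  maternal-ECG cancellation (the cancellation step itself is outside
  this package's scope). A switch restores it for raw-signal studies.
* **Baseline wander**: one sinusoid at 0.15–0.45 Hz, amplitude 0.3.
* **Noise**: white Gaussian noise band-passed to 2–60 Hz, scaled so its
  typical peak (3 σ) equals `noise_amplitude_ratio` × the fetal QRS
  peak. Low-quality recordings additionally receive rectangular burst
  artifacts (0.3–1 s, 3× the base noise level, ~1 per 10 s), emulating
  electrode motion.
* **Quality mapping**: the ratio is drawn per recording from
  HIGH ∈ [0, 0.05], MEDIUM ∈ [0.15, 0.4], LOW ∈ [0.8, 1.2] — a direct
  reading of the annotation wording ("almost no noise", "far less than
  the heartbeat amplitude", "close to the heartbeat amplitude"). All
  ranges are configurable.

What the generator does **not** model: realistic PQRST morphology (only
the sharp QRS spike matters to the quality features), fetal movement,
multi-lead geometry, powerline interference (the analysis band excludes
it), and non-stationary heart rates. Consequently, synthetic classes are
cleanly separable and the pipeline's near-perfect synthetic F1 scores
are an upper bound — they validate the machinery and its direction, not
clinical performance.

Every stage is deterministic given the seed; the dataset generator and
the pipeline derive sub-seeds from a single master seed.

## Pre-processing

Order is fixed: center/normalize → band-pass → despike → segment →
spectrogram; filtering is applied to whole recordings, never per
segment.

* **Normalization**: subtract the mean, divide by max |amplitude|.
* **Band-pass**: linear-phase Kaiser-window FIR, 2–46 Hz, 60 dB
  stopband, 1 Hz transition width (~3600 taps at 1 kHz), applied with
  `fftconvolve(mode="same")` so the integer group delay of the
  odd-length symmetric kernel is exactly compensated.
* **Despiking**: Hampel rule — replace a sample by its 9-sample running
  median when it deviates by more than 8 robust standard deviations.
  The robust scale is max(1.4826·MAD, p99/2.576) of the absolute
  residuals: on smooth oversampled signals the running median equals
  the signal along locally monotone stretches, so the MAD collapses to
  zero and the upper residual tail (waveform-extremum curvature) sets
  the scale. The short window targets millisecond electrode pops; QRS
  complexes (tens of ms) are untouched at every noise level. A long
  (~200 ms) window was rejected: with quiet in-band noise the QRS
  itself is tens of robust SDs from a 200 ms median and gets erased.
* **Spectrograms**: STFT with 128 ms Hann window and 5 ms step,
  magnitude restricted to 2–60 Hz (7 frequency bins at 1 kHz — the
  stated analysis band; rows above the 46 Hz filter edge carry only
  stopband residue, kept as specified rather than "fixed"). Magnitudes
  are mapped to dB re the per-image maximum with a −40 dB floor,
  min-max normalized, rendered through a fixed perceptually uniform
  256-entry colormap, and bilinearly resized to a square 3-channel
  image. The floor clips everything quieter than 1 % of the per-image
  peak to one level: without it the rendering is hypersensitive to
  irrelevant sub-noise-floor detail, and an essentially noiseless
  recording produces images darker than anything a noisier (but still
  high-quality) recording produces — out-of-distribution for an
  autoencoder trained on typical high-quality images. A zero segment
  renders as a uniform image (normalization denominator 0 → 1). The
  rendering is a pure function of the segment.

## Quality features

Twelve features per segment, fixed order: AppEn, SampEn, SpecEn, PEn,
DFA, FD (Katz), HFD (Higuchi), kSQI, sSQI, pSQI, basSQI, AE_MSE.

* **AppEn / SampEn**: m = 2, r = 0.2 × segment sd, Chebyshev distance;
  AppEn includes self-matches, SampEn excludes them (Richman–Moorman
  convention, both template lengths over the first n−m delay vectors).
  Template counting uses a KD-tree; brute-force double-loop oracles pin
  the implementation exactly. SampEn with zero matches returns +inf and
  is capped at ln(pair-count bound) when a feature matrix is assembled.
* **Embedding time scale**: the time-domain entropies (AppEn, SampEn,
  PEn) are computed on the segment decimated 4× (zero-phase FIR
  anti-aliasing) to ~250 Hz. At 1 kHz a < 46 Hz band-limited signal is
  ~10× oversampled and delay-1 embeddings see only the smooth local
  trend — the entropy of *any* such signal is dominated by the sampling
  rate, not by noise. Matching the embedding scale to the in-band
  dynamics is what makes these entropies respond to signal quality;
  this restored the expected HIGH < MEDIUM < LOW ordering. The factor
  is exposed in `EntropyParams`.
* **SpecEn / pSQI / basSQI**: Welch PSD with 2 s Hann windows, 50 %
  overlap (0.5 Hz resolution — needed to resolve basSQI's 0–1 Hz
  baseline band), trapezoidal band integration. SpecEn is normalized by
  log bin count to [0, 1]; pSQI = P[5,15]/P[5,40]; basSQI = 1 −
  P[0,1]/P[0,40].
* **PEn**: order 3, delay 1 (on the decimated signal), ties broken by
  order of appearance, normalized by log 3!.
* **DFA**: DFA-1 — cumulative-sum profile, per-box linear detrending,
  ~16 log-spaced box sizes from 4 to n/4, least-squares slope of
  log F(s) vs log s.
* **FD**: Katz, log₁₀n / (log₁₀n + log₁₀(d/L)); straight lines and
  constants give exactly 1.
* **HFD**: Higuchi with kmax = 10, slope of log L(k) vs log(1/k).
* **kSQI / sSQI**: Pearson (non-excess) kurtosis and skewness.

## Spectrogram autoencoder

A fully convolutional autoencoder with 6 FCN layers (conv/deconv +
batch normalization + ELU) in the encoder and 6 in the decoder plus a
sigmoid output layer; 3×3 kernels throughout; filters
64, 32, 32, 32, 64, 1 | 1, 64, 32, 32, 32, 64 and strides
2, 2, 2, 2, 2, 1 | 1, 2, 2, 2, 2, 2, "same" padding, so a 128×128×3
image maps to a 4×4×1 latent map and back. The advertised output-layer
filter count of 1 cannot emit a 3-channel image, so the output layer
emits one map per input channel — the only way the input and output
shapes can both be 128×128×3.

Implementation is plain numpy (float32): convolutions as 3×3 shifted
GEMMs, transposed convolutions as the exact adjoint (verified by an
inner-product identity test and finite differences), standard
batch-norm statistics with running averages for inference, Adam
(lr 10⁻³), batch size 64, MSE loss, early stopping on a 5-epoch loss
plateau. Training uses **high-quality spectrograms only**, which is the
mechanism of the AE_MSE feature: reconstruction of clean periodic
structure is learned, noisy textures are not, so AE_MSE rises as
quality falls.

A desk-scale mode keeps the identical layer stack on 64×64 images
(latent 2×2); tests and the acceptance script use it with 8 training
epochs so a full pipeline run fits comfortably on one CPU. Trained on
271 high-quality spectrograms for 8 epochs, a typical run gives
held-out mean AE_MSE 0.038 (HIGH) vs 0.053 (MEDIUM) vs 0.072 (LOW).
Held-out comparisons average over 90 segments (3 recordings) per class;
single-recording means are noisy because each recording contributes one
noise-ratio and one heart-rate draw.

## Feature selection (MCFS)

k-NN affinity graph (k = 5) on standardized rows, heat-kernel weights
with bandwidth = median pairwise distance, symmetrized by max; the
generalized eigenproblem L y = λ D y is solved densely and the
n_clusters = 3 smallest non-trivial eigenvectors kept; each eigenvector
is regressed on the standardized features by least-angle regression at
the densest solution (all 12 coefficients active); the MCFS score of a
feature is its maximum absolute coefficient across eigenvectors; the
top 5 are selected, ties broken by fixed feature order. Standardization
makes scores invariant to affine column rescaling. On strongly
separated synthetic data the selected set is dominated by the entropy
features plus kSQI/sSQI/DFA; which five win can differ from clinical
data, where the exact ranking depends on the noise mix.

## SOM classifier

8×8 lattice, initial learning rate 0.5, 100 000 online iterations,
bubble neighborhood, trained on standardized selected features
(statistics stored in the model so new segments are scaled identically).
Where the training procedure is underdetermined the choices are:
lr(t) = lr0 / (1 + t/(T/2)); bubble radius (Chebyshev on the grid)
linear from half the grid down to 1; weights initialized
standard-normal; winner ties broken lexicographically. Neuron labeling
samples three winners per neuron (majority vote); neurons with fewer
winners take the majority of what they have; label ties resolve to LOW
(the application prefers removal sensitivity — a false LOW costs one
clean segment, a missed LOW pollutes the FHR trace); empty neurons
inherit the nearest labeled neuron by grid distance, so classification
always returns a label. Datasets are balanced before training by
seeded random undersampling to the minority class count.

## Evaluation

Classification uses per-class precision/recall/F1, weighted averages
and a 3×3 confusion matrix (rows true, columns predicted, order HIGH,
MEDIUM, LOW), with the train = test protocol that is conventional for
unsupervised clustering evaluation.

The FHR experiment estimates the mean fetal RR interval (FRRI, samples)
per 3 s segment with a deliberately simple documented detector: square
→ 50 ms moving average → peaks above 0.4 × the smoothed maximum with a
250 ms refractory period → mean successive-peak interval; fewer than
two peaks yields a missing-estimate sentinel. Reference FRRI comes from
the generator's ground-truth beat times. Reported metrics: RMSE of FRRI
(in samples — native units of the estimator; no attempt is made to
reproduce the original study's printed RMSE scale), AAE of FHR
(|60·Fs/F̂RRI − 60·Fs/FRRI|, beats/min) and the removal rate. Segments
without a valid estimate or reference are excluded from both branches,
so the fair comparator for the removal rate is the LOW fraction among
*evaluated* segments, which the experiment reports alongside the
injected fraction. Mixed-quality recordings interleave HIGH- and
LOW-range 3 s blocks and are segmented without overlap so segments
align with blocks.

## Problem sizes and runtime

Tests and the acceptance script run the full protocol — 271 segments
per class (813 total), five seeds in the acceptance suite — with the
desk-scale autoencoder (64×64, 8 epochs). One full pipeline run takes
roughly 1.5–2 minutes on one CPU; the complete test suite and the
acceptance script each stay well inside typical CI budgets.

## Known limitations

* Synthetic separability overstates clinical performance by design;
  only directions and mechanisms (entropy orderings, AE_MSE separation,
  error reduction after removal) transfer.
* The FRRI estimator is a stand-in for a full FHR algorithm; it fails
  (by construction, usefully) on heavy noise rather than degrading
  gracefully.
* Maternal-ECG cancellation is not implemented; with the maternal
  component enabled, the maternal QRS dominates every feature and the
  quality classes reflect the abdominal mixture, not the fetal signal.
* The MCFS ranking on synthetic data need not match rankings on
  clinical data; the pipeline treats the selected set as data-dependent.
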