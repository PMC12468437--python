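# Methods

## Signal model of the simulator

A cardiac cycle of period `T = 60/heart_rate` seconds contains two
transients:

* **S1** (atrioventricular valve closure) at the cycle onset — a
  Gaussian-enveloped sinusoid, 50 Hz center frequency, 90 ms duration,
  unit amplitude;
* **S2** (semilunar valve closure) at `0.35·T` after S1 — 80 Hz, 70 ms,
  0.8× the S1 amplitude.

The envelope is `exp(-(t-μ)²/2σ²)` with `σ = duration/6`, so the
transient peaks at its midpoint and is ~3σ down at its edges. Cycle
onsets are placed at `k·T` for `k = 0 … floor(duration·heart_rate/60)-1`
(optionally jittered with Gaussian timing noise, default 5 ms in
generated corpora, 0 in unit tests so the beat-count law is exact).
These values mimic textbook phonocardiogram morphology; heart-sound
energy sits below ~1 kHz, which motivates the 4 kHz default sample
rate (configurable; Nyquist comfortably above all synthesized content).

**Murmurs.** An abnormal recording adds, per cycle, white noise
band-passed (4th-order Butterworth, zero-phase) to a condition-specific
band, Hann-windowed over the central portion of the S1-offset→S2-onset
gap. The six presets (VSD, ASD, PDA, TOF, PS, AS) differ in band
(120–450 Hz range) and relative gain (0.30–0.45 of the S1 amplitude);
the real corpus being emulated describes its murmurs only
qualitatively, so the presets are plausible mid-frequency systolic
murmurs rather than hemodynamic simulations. `murmur_gain = 0` defines
the normal pseudo-preset; the label is derived from the gain, which is
what the no-leakage null test exploits.

Background noise is additive white Gaussian (`noise_sd = 0.01`,
emulating a clean clinical recording); the sum is peak-normalized to
0.9 and written as 16-bit PCM mono WAV. Every recording's seed is
derived from the corpus master seed via `numpy` `SeedSequence`, stored
in the manifest, so any single file is regenerable in isolation.

**What the simulator does not model:** diastolic murmurs, respiration,
ambient/handling noise, sensor transfer functions, inter-patient
anatomical variability, or split S2. Synthetic murmurs are
band-limited, stationary within the systolic window and identical in
distribution across cycles — far easier to detect than clinical
murmurs. Perfect accuracy on synthetic corpora therefore demonstrates
that the pipeline is wired correctly and can learn a separable
acoustic signature, not that it would reach comparable accuracy on
real pediatric auscultation.

## Features

* **MFCC** — 25 ms Hann frames, 10 ms hop, power spectrum (FFT length
  max(256, frame)), 26 triangular mel filters (HTK mel scale,
  20 Hz–Nyquist), `log` floored at `1e-10`, orthonormal DCT-II, first
  13 coefficients. The frame count obeys
  `n_frames = 1 + floor((N - frame)/hop)`.
* **STFT** — same framing; magnitudes over 0…Nyquist, frames restricted
  to windows fully inside the signal so framing arithmetic matches the
  MFCC path.
* **Wavelet scalogram** — continuous Morlet transform at 64 scales,
  log-spaced so pseudo-frequencies cover ~20 Hz to Nyquist; row 0 is
  the highest frequency.
* **Image rendering** — log-compress (same floor), bilinear resize to
  the target size, then min–max normalize and replicate the channel
  three times. Normalizing *after* the resize keeps the output range
  exactly [0, 1]; a constant matrix maps to all zeros by decision (a
  featureless input should be a featureless image). Grayscale
  replication rather than a colormap keeps rendering deterministic and
  library-independent. MFCC matrices are rendered from their absolute
  values since cepstral coefficients are signed.

The log floor guarantees no NaN/Inf under any input, including all-zero
signals.

## Architectures and training

The three builders return backend-independent layer specifications (see
README for the layer tables). Choices the architecture descriptions
leave open, resolved here as package defaults:

* convolutions use "valid" padding, stride 1;
* the pre-softmax head for model1/model3 is Dense(64, ReLU),
  configurable — the descriptions say only "fully connected layers";
* the model3 conv→LSTM bridge reshapes the `(H', W', C)` feature map to
  `H'` timesteps × `W'·C` features (rows as time), preserving the
  temporal ordering when images carry time on one axis;
* model3 defaults to 50 epochs (100 via flag); learning rate defaults
  to Adam's 1e-3.

Parameter counting is closed-form per layer (dense `(n_in+1)·u`, conv
`(k²c_in+1)·f`, LSTM `4(u(n_in+u)+u)`, batch-norm `2c` trainable) and is
tested against brute-force per-weight enumeration and against the
arrays the backend actually allocates. With these closed forms the
builders report 344,258 (model1 at 598×13 input), 3,305,346 (model2)
and 372,802 (model3) trainable parameters. Published counts for
comparable models are not reproducible from prose architecture
descriptions under any single standard padding/head convention, so the
builders always report their true counts.

The backend is pure numpy: im2col convolution, 2×2 argmax pooling,
batch normalization with running statistics, full backpropagation
through time for the LSTM (gate order i, f, g, o; forget bias 1;
Glorot/orthogonal initialization), inverted dropout, Adam. Every
layer's backward pass is verified against central finite differences
(tolerance 1e-6 … 1e-5). Training is deterministic given (seed, data,
architecture) in single-threaded execution; the softmax/cross-entropy
gradient is computed jointly as `(p - y)/batch` for numerical
stability. With learning rate 0 the returned weights equal the initial
weights; the recorded per-epoch loss still fluctuates because dropout
masks differ per batch.

## Evaluation protocol

Positive class = abnormal (the patient). Zero-denominator metrics
(e.g. sensitivity of a fold with no positives) return an explicit
`None`, are excluded from averages, and the number of affected folds is
reported — silent NaN propagation is never allowed. Reported tables
round to 4 decimal places with halves away from zero
(`round_half_up`), the convention used in published performance tables;
Python's float `round` would turn 0.91665 into 0.9166.

Cross-validation is stratified k-fold (k = 10 by default; fold sizes
differ by at most one, class ratios within one example of global). The
repeated protocol draws `n_per_class` recordings per class (default
218, without replacement within an iteration), runs k-fold CV on the
draw, and repeats (default 50 iterations), reporting mean ± sd of the
per-iteration fold means (unweighted). The 218+218 default presumes a
segment-level pool larger than the 60-recording corpus; the windowing
utility (`segment_recording`, full windows only, tails discarded, so
every segment is statistically homogeneous) builds such pools from
longer recordings, and a `replace` flag permits oversampling when the
pool is smaller. Both the 8:1:1 stratified split (largest-remainder
rounding per class, ties broken train→validation→test) and the k-fold
protocol are implemented; which one a run uses is a CLI/config choice.

The extractor-comparison harness fixes the train/test split and the
classifier head across extractors, so the rows form a paired comparison
in which only the representation varies.

## Problem sizes in tests and scripts

Unit and acceptance tests run scaled-down study conditions chosen to
keep the suite fast on one CPU while preserving the pipeline's
structure: two-second recordings (murmur structure is per-cycle, so
duration only multiplies cycles), 24-recording training fixtures,
64×64 images, 10–15 epochs for the hybrid model, and the repeated
protocol at iterations=2 / n_per_class=5 with a small LSTM or logistic
head. The full-scale defaults (six-second recordings, 60-recording
corpus, 218+218 × 50 iterations, 50–100 epochs) remain the package
defaults and run unchanged — they are simply not exercised inside the
test suite.

## Known limitations

* The numpy backend is CPU-only and single-threaded by design;
  full-scale model2 (128×128 images, 100 epochs) on large corpora is
  slow compared to a GPU framework, though correct.
* The simulator's class separation is optimistic (see above); results
  on synthetic corpora upper-bound nothing about clinical data.
* Only binary classification is supported; the six conditions tag
  recordings but are not prediction targets.
* Audio I/O is deliberately restricted to mono 16-bit PCM WAV.
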