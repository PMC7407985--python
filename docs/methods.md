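# Methods

`semgss` re-implements a silent-speech decoding pipeline for multi-channel
surface electromyography (sEMG): signals recorded from articulatory muscles
while a subject *imagines* speaking are conditioned, turned into per-channel
spectrogram images, mapped to fixed-length feature vectors, and classified
into word labels by one of three neural decoders. Because no public corpus
of silent-speech sEMG exists, the package ships a synthetic generator that
reproduces the statistical structure the pipeline assumes, and every stage
is specified and tested against that generator.

## Signal model and synthetic data

Silent-speech sEMG is low amplitude (generally below 1 mV) and band-limited
(≤ 300 Hz), sampled here at 1000 Hz on 6 channels. A word "sample" is a
pre-segmented 2 s epoch. The generator synthesizes, per channel,

* a **burst**: white Gaussian noise gated by a raised-cosine envelope
  (onset, duration, amplitude in mV per channel), then zero-phase
  bandpassed to the class's burst band. Band-limiting is deliberately the
  *last* step so the burst's power stays inside the band no matter how
  short the gate is; the result is rescaled to the gated noise's power so
  the envelope amplitude keeps its meaning in mV;
* **contamination**: 50 Hz powerline with harmonics (amplitudes falling as
  1/k), a sub-0.5 Hz drift sinusoid, a DC offset, and broadband white
  noise. Default amplitudes (0.2 mV powerline, 0.5 mV drift, 0.3 mV DC,
  0.02 mV white) are representative of desk-quality skin-electrode
  recordings and were fixed once, up front.

Word classes differ in which channels burst strongly (a class-dependent
subset), in burst band (stepped 60 Hz-wide bands from 30 Hz upward) and in
onset staggering — the three cues distinct articulatory muscle synergies
present to a decoder. Sample duration (2.0 s) is a desk-scale choice:
long enough for a multi-column spectrogram at the default 512-sample
window, short enough for fast tests. The generator is fully seeded; a
dataset derives one independent child seed per sample from the master seed.

What the generator does **not** model: motor-unit action-potential shapes,
electrode impedance and its drift, bipolar-vs-unipolar derivation,
inter-subject variability, or label noise. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that it recovers
class structure of the kind it assumes — not that the reported synthetic
accuracies transfer to real recordings.

## Conditioning

Per channel, in order:

1. **Butterworth bandpass 0.15–300 Hz**, overall order 8 (4th-order
   prototype), realized as second-order sections and applied
   forward–backward (zero phase) so burst timing is preserved for the
   spectrograms. The extreme 0.15 Hz edge settles over seconds; filtering
   uses maximal reflection padding, and residual slow transients on short
   epochs are subsequently removed by the detrending stage.
2. **Comb notch**: cascaded second-order IIR notches at 50·k Hz
   (k up to min(bp_high, Nyquist)), constant 2 Hz bandwidth (Q = 25 at
   50 Hz), zero phase.
3. **Quadratic variation reduction (QVR)**: z = z̃ − y where
   (I + λDᵀD) y = z̃, D the first-difference operator and λ = 100. The
   system matrix is symmetric positive-definite tridiagonal and is solved
   with a banded Cholesky factorization in O(n); a dense explicit-inverse
   path (n ≤ 2000) is kept purely as a cross-check oracle. λ = 0 and
   constant inputs give exactly zero output; λ → ∞ tends to mean removal.

Frequency-gain contracts are verified in steady state: a 30 s sinusoid is
filtered, and the gain is read off the central third (plain RMS in the
passband; quadrature demodulation at deeply attenuated frequencies, where
additive edge leakage would otherwise dominate the measurement). On a 2 s
epoch, full-signal RMS would largely measure the 0.15 Hz edge transient
rather than the filter.

## Spectrogram imaging

Each conditioned channel is transformed to `|STFT(x)|²` with a periodic
Hann window of 512 samples, 50% overlap, and no boundary padding — each
column is exactly `|FFT(w ⊙ segment)|²`, with `floor((n − 512)/256) + 1`
columns. The nominal parameter tuple also lists an FFT length of 64, which
a standard STFT cannot realize with a 512-sample window; the effective FFT
length is `max(win_len, nfft)` and a configured shorter value is kept as
metadata and flagged with a warning.

Rendering: optional log compression `10·log₁₀(P + 1e−12)` (on by
default), min–max normalization to [0, 1] (a constant matrix maps to the
all-0.5 raster instead of dividing by zero), then bilinear resize to
299 × 299 — the input geometry of large pretrained image backbones. For
linear scaling the rendering is exactly scale-invariant; under log scaling
a positive scale factor becomes an additive offset that the normalization
also cancels (up to ε).

## Feature extraction

Each channel image maps to a 1000-dimensional vector; the six vectors form
a 6 × 1000 sequence (one step per channel, acquisition order) whose
row-major flattening is the 6000-long concatenated view. Two backends
share this contract:

* `pretrained_backbone`: the 1000-way classification-head activations of a
  large pretrained image classifier. Weights are a plug-in; without them
  the backend raises a backend-unavailable error naming the fallback.
* `deterministic_fallback` (default): 8×8 and 4×4 grids of block means
  (80 numbers preserving coarse image geometry) → fixed seeded Gaussian
  matrix (scaled 1/√80) → 1000 dims → ReLU. The pre-activation map is
  linear, so the zero image maps to zero (plus the optional bias) and the
  extractor is Lipschitz with constant the projection's operator norm.
  A histogram descriptor was considered and rejected: it is neither linear
  nor Lipschitz, which would break both properties exactly.

Per-dimension standardization statistics are computed on the training
split only and reused for validation/test (no leakage); zero-variance
dimensions standardize to zero.

## Decoders

Three families share cross-entropy loss, batch size 32, initial learning
rate 1e−3, ReLU activations and batch normalization, and differ as:

| family | optimizer | dropout | topology (defaults) |
|--------|-----------|---------|---------------------|
| mlp    | adam      | 0.2     | dense 1024 → 256 → softmax |
| cnn    | adadelta  | 0.5     | reshape 6×1000×1 → conv 32@3×7 → pool 1×2 → conv 64@3×5 → pool 1×2 → dense 256 → softmax |
| blstm  | rmsprop   | 0.2     | 3 bidirectional LSTM layers of 128 units over the 6-step sequence → dense 128 → 64 → softmax |

Exact hidden sizes are configurable; the defaults balance capacity against
desk-scale training cost. ReLU applies to dense layers; recurrent cells
keep their canonical sigmoid/tanh gates. The networks, including the
bidirectional LSTM with backpropagation through time, batch normalization,
inverted dropout and the three optimizers, are implemented directly in
NumPy; every analytic gradient is pinned against central finite
differences in the test suite, and training is fully seeded (shuffling,
initialization and dropout each draw from seeded generators), so a fixed
(data, config, seed) triple reproduces results bit-for-bit on a fixed
BLAS.

**Training schedule.** Validation loss is monitored (validation drives
both rules). Reduce-on-plateau: factor 0.2 after 20 stagnant epochs,
floored at 0.5e−6; the plateau counter resets on improvement and on each
reduction. Early stopping: after 80 stagnant epochs; its counter resets
only on improvement. Best-validation-loss weights are restored at the
end. Training-epoch metrics are running minibatch averages; validation
metrics are a full inference pass.

**Splitting.** 7:2:1 train/validate/test, stratified per class with
largest-remainder rounding (100 samples → exactly 70/20/10), seeded;
classes with fewer samples than split parts are rejected explicitly.

## Pipeline, evaluation and problem sizes

The orchestrator persists each stage's artifact (HDF5 recordings and
features, CSV training curves, JSON evaluation and manifest with SHA-256
hashes and seeds) and can resume from completed stages, leaving skipped
artifacts byte-identical. Confusion matrices are stored as raw counts
(rows = true class); the row-normalized view and per-class recall are
derived. Accuracy ≡ trace/total by construction and is re-validated on
every report.

Default desk-scale study: 3 classes × 150 samples × 2 s, fallback
extractor, all three families, schedule shortened to max 25 epochs
(plateau patience 8, early-stop patience 15). At this scale all three
families exceed 0.99 validation accuracy within ~6 epochs and reach 1.00
test accuracy; the full run takes roughly 5 minutes on one CPU, the CNN
(Adadelta) being the slowest family. The full-length schedule values
remain the `TrainingSchedule` defaults and their semantics are tested
against hand-computed traces.

## Known limitations

* The fallback extractor is a fixed random projection, not a trained
  backbone; it preserves coarse spatial structure but none of the semantic
  priors of a pretrained classifier.
* Real-recording phenomena absent from the generator (above) mean synthetic
  accuracies are an upper bound on pipeline health, not a forecast.
* Adadelta at learning rate 1e−3 descends slowly on small problems; the CNN
  therefore rarely triggers early stopping at desk scale.
* The dense QVR path is O(n³) and capped at n = 2000 by design.
* Real-time streaming inference and hardware integration are out of scope.
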