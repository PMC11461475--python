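# Methods

This note records the model, the statistical procedures, and the design
choices made where more than one reasonable implementation existed, along
with what the synthetic-data experiments do and do not demonstrate.

## Neuron model

The adaptive leaky integrate-and-fire (AdLIF) neuron is integrated with an
exponential-Euler scheme at step `Δt` (the frontend hop, 1–5 ms; 2 ms in
all analysis configurations so that the full gamma range of interest stays
below the 250 Hz Nyquist frequency):

    u[t] = α (u[t−1] − s[t−1]) + (1 − α)(I[t] − w[t−1]),   α = exp(−Δt/τ_u)
    w[t] = β (w[t−1] + b s[t−1]) + (1 − β) a u[t−1],       β = exp(−Δt/τ_w)
    s[t] = [u[t] ≥ 1]

starting from `u = w = s = 0`.  The model is dimensionless: threshold 1,
rest 0, input resistance absorbed into the stimulus scale.  Parameters are
constrained to biological boxes (`τ_u ∈ [3, 25]` ms, `τ_w ∈ [30, 350]` ms,
`a ∈ [−0.5, 5]`, `b ∈ [0, 2]`) by **projection after every optimizer
step**; projection keeps gradients untouched and is idempotent, which the
tests assert directly.  On top of the box we enforce stability of the
2×2 subthreshold linear map (spectral radius < 1) constructively, shrinking
`a` toward zero when violated.  Analysis of the map shows the box is
intrinsically stable for `Δt ≤ 5 ms`; the projection only binds for coarser
steps.

Neurons without spike-frequency adaptation (SFA) have `a = b = 0` enforced
by a fixed mask, reducing exactly to LIF; per-layer SFA fractions choose
which neurons adapt, drawn once from the layer's mask seed.  Trainability
follows the architecture's roles: auditory nerve fibers train only `τ_u`;
AdLIF neurons additionally train `τ_w`, `a`, `b`.

The equivalent spike-response-model kernels (membrane response to an input
pulse and to an emitted spike) are obtained by direct simulation from rest
and exported for inspection; with `a = 0.5, b = 1.5, τ_u = 5 ms,
τ_w = 30 ms` the input kernel shows the characteristic positive peak
followed by a single undershoot below rest.  Because the pulse
normalization (unit height vs. unit area) is a convention, kernels are
reported up to input scaling.

## Surrogate gradient and training

The spike threshold has an almost-everywhere-zero derivative, so the
backward pass substitutes the boxcar surrogate `∂s/∂u = 0.5` on
`|u − 1| ≤ 0.5`, 0 elsewhere.  The entire pipeline — auditory CNN, nerve
fibers, AdLIF layers, pooling and head — is implemented in NumPy with
hand-derived reverse-mode gradients (backpropagation through time for the
spiking layers).  Correctness is established two ways: the differentiable
modules are checked against central finite differences, and the spiking
BPTT — which finite differences cannot probe, since the surrogate *defines*
the relaxed derivative — is checked against an independent forward-mode
(tangent propagation) implementation of the same chain rule; the two agree
to relative 1e−9.  All computation is double precision: at desk scale this
costs little and keeps the training path directly comparable to the
float64 oracles.

Masks, Dale signs and the zero recurrent diagonal are structural: the
optimizer updates raw weight buffers, and the effective weights are formed
functionally as `mask ⊙ sign ⊙ |raw|` (Dale) or `mask ⊙ raw`, so no
gradient step can disturb them.  Under Dale's law the excitatory count for
an E/I odds ratio `r` is `ceil(N·r/(1+r))` over a seeded permutation, and
auditory nerve fibers are all excitatory.

Weight initialization is zero-mean normal scaled by `1/√fan-in`, times a
gain (default 8).  The gain compensates for the sparsity of binary spike
inputs: with input spike densities of order 0.01–0.02, a unit-gain
fan-in-scaled init leaves deep layers silent, and a silent layer provides
no surrogate-gradient window (`u` never reaches 0.5) for training to
recover from.  Gain 8 ≈ `1/√density` gives an untrained network
alive-but-attenuating activity across layers — matching the qualitative
observation that untrained networks progressively lose structured activity
with depth — while leaving enough gradient for the rate regularizer and the
task loss to revive deep layers during training.

Training uses Adam (default learning rate 3e−3), global-norm gradient
clipping at 5, per-utterance CTC losses normalized by label length before
batch averaging, and the firing-rate regularizer

    L_reg = (1/BL) Σ_b Σ_l (1/N_l) Σ_n ReLU(f_min − f) + ReLU(f − f_max)

with `f_min = 0.5 Hz`, `f_max` the simulation Nyquist, applied to all
spiking layers including the nerve (configurable), rates computed on true
(unpadded) utterance durations.  The regularizer's weight relative to CTC
is 1.0 by default; no canonical value exists, and the setting is recorded
in the config.  Variable-length utterances are zero-padded; CTC and rate
computations are masked to true lengths.

## Speech pipeline specifics

- **Mel frontend**: hand-rolled HTK-style triangular filterbank (80 filters
  over 0–8 kHz, 25 ms Hann window, FFT 512, log compression).  A 2 ms hop
  yields a 500 Hz frame rate that doubles as the SNN time step.
- **Auditory CNN**: one 2-d convolution, default 16 channels, 7×7 kernel,
  no feature padding (80 → 74 positions, so each output signal pools seven
  adjacent Mel bins, the bandwidth suggested by cochlear tuning-sharpness
  data), symmetric time padding so the frame count is unchanged, followed
  by layer normalization over fibers, channel dropout (0.15) and LeakyReLU.
- **Head**: average pooling by `40/Δt` (pooled rate exactly 25 Hz for every
  `Δt ∈ {1, 2, 5}` ms), two fully connected stages with LeakyReLU into the
  phoneme-feature space, and a final log-softmax projection to the class
  count plus CTC blank (40 outputs in the full-size configuration).
- **Decoding**: greedy best-path CTC (per-frame argmax, merge repeats, drop
  blanks); the error rate is the Levenshtein distance over reference length
  in percent.  No beam search or language model, keeping the measured error
  a direct readout of the encoder.

## Population signals and PAC statistics

Per layer and utterance, binary spike trains are summed per time step and
z-scored over time (a degenerate, constant series is rejected rather than
silently normalized).  Band decomposition uses zero-phase (filtfilt)
windowed-sinc FIR filters over the canonical bands: delta 0.5–4, theta
4–8, alpha 8–13, beta 13–30 Hz as modulating bands; low gamma 30–80 and
high gamma 80–150 Hz as modulated bands.  **Filter order** is the larger of
(a) three cycles of the band's low edge and (b) the length at which the
Hamming transition width falls below half the band's width, capped by what
filtfilt admits for the signal length.  Choice (b) matters: a filter sized
by rule (a) alone has a ~9 Hz transition at the alpha band's 8 Hz edge and
leaks a 6 Hz modulator into the alpha filter, misattributing couplings.
After filtering, phase and envelope come from the analytic (Hilbert)
signal, and half a filter span is trimmed from each end before any metric
is computed.

Two PAC metrics are computed per scenario: the modulation index
(KL divergence between the phase-binned mean-amplitude profile and the
uniform profile, normalized by `log n_bins`; 18 bins of 20°, the convention
of the metric's literature) and the mean vector length
`|mean(A e^{iφ})|`.  Significance uses cut-and-swap surrogates: the
amplitude series is cut at a uniform interior index and the two segments
swapped (a circular shift), the metric recomputed against the unchanged
phase series — 10,000 surrogates by default — and the p-value is the upper
tail of a Gaussian fitted by moments to the surrogate values.  A scenario
is significant only when **both** metrics give p < 0.05.  Scenario
enumeration covers every intra-layer pair and every inter-layer pair with
the amplitude layer strictly downstream, crossed with the 4×2 band grid
and the utterance set: 4 populations × 8 band pairs × 64 utterances =
5,120 scenarios in the reference configuration.

Calibration, measured by the acceptance machinery on independent-noise
pairs (theta phase vs. high-gamma amplitude, 10 s at 500 Hz, 500
surrogates): single-metric false-positive rates of roughly 5–7%, and a
dual-metric rate near 2%.  The single-metric rates sit slightly above the
nominal 5% because both null distributions are right-skewed (the MI null is
chi-square-like, the MVL null Rayleigh-like) while the p-value comes from a
symmetric Gaussian fit — the moment fit is mildly anti-conservative in the
upper tail, and more so for slow modulating bands whose envelopes have long
autocorrelation (delta or beta with low gamma reach ~7–8% for MI).  This
anti-conservatism is inherent to the Gaussian-fit procedure and is exactly
why the dual-metric rule, which stays conservative everywhere, is the
significance criterion.

## Synthetic data

The generators define the study conditions:

- **Coupled-oscillation signals** for validating the PAC stack: the slow
  modulator is *band-limited Gaussian noise* (default 6 ± 1 Hz) whose
  analytic phase φ drives the gamma envelope,
  `x = (1 + depth·cos φ)·cos(2π f_amp t) + cos φ + pink noise` at a given
  SNR (default 10 dB).  Two deliberate choices: a strictly periodic
  modulator would make cut-and-swap surrogates blind to the coupling (a
  circular shift of a periodic envelope only moves the preferred phase,
  invisible to both metrics) and would keep the filtered phase coherent
  across the whole record, inflating the surrogate null; and a white
  background would leave the modulator's spectral tails as the dominant
  low-frequency content, smearing the coupling across neighboring bands —
  pink (1/f) noise is both the realistic EEG-like choice and what confines
  the planted coupling to its own band.  At default settings the detection
  rate is ~100% and the planted (theta, low-gamma) pair wins the 8-pair
  band grid on ≳95% of seeds.
- **Poisson rasters** (independent Bernoulli per step) fix the rate-,
  histogram- and population-signal arithmetic.
- **Tone-sequence corpus**: each utterance concatenates 2–5 pure tones
  (400/800/1600/3200 Hz, 60–100 ms, jittered, 5–20 ms gaps, −30 dB noise
  floor, 50 ms silence padding) whose symbol sequence is the transcript.
  200 training utterances and a held-out set of 40 make a task a 3×128
  toy pipeline learns to <10% symbol error within ~10 training epochs on
  one CPU.  The corpus exercises the full CTC training loop, not phonetic
  realism: tones are stationary and spectrally disjoint, so passing it
  shows the machinery trains end to end, not that the architecture handles
  coarticulated speech.
- **Noise inputs**: uniform white noise, and "babble-like" noise built from
  amplitude-modulated narrowband processes (2–6 Hz modulators over
  voice-band carriers) that mimic the slow envelope structure of
  overlapping talkers without symbolic content.

What the passing experiments show — and what they do not.  They show the
dynamics are implemented exactly (oracle equivalence), the gradients are
the surrogate chain rule (forward-mode agreement), the PAC statistics are
calibrated and powerful on signals with known ground truth, training
recovers the planted symbol structure, and the directional phenomena
(noise quieter than in-distribution input on a trained net; activity decay
across untrained layers; the rate regularizer pulling neurons into band)
hold at toy scale.  They do not show phoneme-level speech recognition
performance, nor that oscillations emerge in a large trained network —
those require real speech corpora and full-size training runs outside this
package's scope.

## Numerical and degenerate-input policies

Rejected inputs raise `ValueError` with a reason: non-finite stimuli,
non-positive `Δt`, empty stimulus series, waveforms shorter than one
analysis window, rasters with non-binary entries, constant population
signals, bands at or above Nyquist, signals shorter than the filter span,
label sequences that cannot fit their CTC frame budget, empty references
in error-rate computation, zero-spread surrogate distributions.  Empty
phase bins contribute zero mean amplitude provided at least one bin is
occupied.  CTC runs in log space throughout; the p-value from the Gaussian
fit is not floored, and exact zeros should be read as "below 1/n_surrogates".

## Scale of the shipped experiments

The default test and acceptance runs use: 200 training / 40 evaluation
utterances, a 2-channel CNN (148 fibers), three 128-neuron layers, 500
calibration trials at 500 surrogates, 100 detection seeds, and
10,000-surrogate PAC tests only where a single scenario is examined.
These sizes were chosen so the full suite completes in minutes on a single
CPU while every statistical assertion retains a meaningful sampling margin.
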