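# Methods

This note documents the models implemented in `neurovox`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not demonstrate.

## Differentiable source–filter synthesizer

The synthesizer maps 18 per-frame speech parameters to a magnitude
spectrogram (125 frames/s, K frequency bins over [0, 8 kHz]; K = 256 for a
female voice profile, 512 for male). Two pathways are mixed by the voice
weight α ∈ [0, 1]:

* **Voice pathway.** A harmonic excitation at pitch f0 — up to 80 harmonics,
  partials above 8 kHz removed — filtered by N = 6 formant filters. Each
  filter is a shifted and scaled copy of a learnable unimodal prototype
  G_i(f): F_i(f) = a_i · G_i((b_proto/b_i)(f − f_i) + f_proto), peaking at
  the centre frequency f_i with half-power width b_i. Bandwidths are tied to
  centre frequencies by a piecewise-linear relation
  b_i = a·(f_i − f_θ) + b_0 above the threshold f_θ and b_0 below it.
* **Noise pathway.** White-noise excitation filtered by a broadband filter
  (own prototype; centre, bandwidth > 2 kHz and amplitude are free per
  frame) plus the same six formant filters.

The output is S(f) = L·[α·V + (1−α)·U] + B(f) with per-frame loudness L and
a learnable stationary background spectrum B ≥ 0. Learnable speaker
parameters: 7 prototypes × 80 samples (560), 6 bandwidth triples (18), and
K background bins — 834 scalars for the female profile, 1,090 for male.

**Constraint parameterization.** Prototype samples must rise monotonically
to a single peak of exactly 1 and then fall. We build them from per-step
sigmoid ratios (cumulative products away from a fixed peak index), so no
gradient step can violate unimodality. Threshold frequencies live in
[0, f_max] via a sigmoid; slopes, baseline bandwidths and the background use
softplus. The peak index of each prototype is an integer hyperparameter, not
a counted learnable.

**Frequency-domain harmonic excitation.** The harmonic excitation is
synthesized directly on the spectrogram grid: each in-band harmonic k
contributes a unit-peak Gaussian kernel (σ = 1.2 bins, matching the mainlobe
scale a 2K-sample Hann analysis window would produce) centred at k·f0. This
is spectrally equivalent at the analysis resolution to rendering
Σ_k sin(2πk·φ(t)) at audio rate and taking the short-time transform, but it
is far cheaper on CPU and its gradient with respect to f0 is smooth and
analytic (implemented as a fused operation with an explicit Jacobian).
Audio-rate rendering remains available through Griffin–Lim inversion of the
magnitude spectrogram.

**Noise excitation.** Per-bin magnitudes of Gaussian white noise are
Rayleigh distributed; we sample them directly with unit expected power,
seeded. Passing `seed=None` substitutes the expected magnitude √π/2 in every
bin ("mean-field" synthesis). Training and evaluation use mean-field
synthesis: the noise realization in a recorded target is unpredictable, so
the expectation is the right point prediction, and sampling fresh noise in
the reconstruction injects persistent gradient noise that measurably
destabilizes voice-weight recovery. Seeded sampling is used when rendering
audio.

**Non-smooth points.** The piecewise-linear prototypes make filter responses
non-differentiable exactly at the sample knots, and the bandwidth relation
at f_θ; gradients use the right-hand slope there. Finite-difference checks
agree to <1e-3 relative error away from knots.

## Loss stack

* **MSS**: per-cell means of |x−y| and |log x − log y| on the linear
  spectrogram and on an 80-band triangular Mel projection, summed over the
  two scales. The mean convention keeps L_MSS O(1), the scale on which the
  STOI weight (1.2 on a value in [−1, 1]) meaningfully trades off against
  it. Logs are floored at 1e-6 of the reference dynamic range.
* **STOI+**: 15 one-third-octave bands (lowest centre 150 Hz, highest
  ≈4.3 kHz; edges rounded to the nearest DFT bin, ties downward), 30-frame
  envelope segments, mean Pearson correlation over all bands and frames; no
  clipping or normalization. Zero-variance segments contribute 0. The loss
  is its negative.
* **Supervision**: ‖f̃0−f0‖² + Σᵢβᵢ‖f̃ᵢ−fᵢ‖² in Hz for pitch and formants
  1–4 (β = 0.1, 0.06, 0.03, 0.02), squared norms averaged over supervised
  frames, restricted to voiced frames when a voicing mask is supplied —
  pitch trackers emit no reference in unvoiced spans, and the synthetic
  ground truth free-runs there.
* **Reference** (decoder training): Σⱼ λⱼ‖C̃ⱼ−Cⱼ‖² over all 18 parameters
  (per-frame means) with the tuned per-parameter weights (voice weight 1.8, loudness 1.5,
  pitch 0.4, formant frequencies 3/1.8/1.2/0.9/0.6/0.3, formant amplitudes
  4/2.4/1.2/0.9/0.6/0.3, broadband 10/4/4). Frequency-valued parameters are
  compared on their normalized [0, 1] ranges: the weights are only mutually
  consistent on O(1) scales.
* **Totals**: auto-encoder L = L_MSS + 1.2·L_STOI + 0.1·L_supervision;
  decoder adds 1.0·L_reference. Adam, lr 1e-3, β = (0.9, 0.999) by default.

## Speech encoder

Temporal convolutions (default 5 layers, kernel 5, 64 channels) over the
standardized log spectrogram, followed by per-frame channel MLP heads.
Frequency outputs use sigmoid activations de-normalized to configured
ranges (f0 50–400 Hz, f1 200–1000, f2 500–3000, f3 1200–4000, f4 2000–5000,
f5 3000–7000, f6 4000–8000, broadband centre 1000–8000); amplitudes and
loudness use softplus; the voice weight a sigmoid; the broadband bandwidth
maps onto (2000, 8000] Hz.

The pitch head fuses four feature streams: the shared trunk, a Mel-branch
(two conv layers), the low-frequency band of the linear spectrogram
(≤600 Hz), and a cepstral band whose quefrencies span the f0 search range.
It also receives an explicit cepstral-peak pitch estimate (parabolic
sub-sample refinement, 5-frame median filter for octave-glitch removal) and
its prominence; the estimate's logit biases the output sigmoid and the
head's output layer is zero-initialized, so the untrained encoder already
emits the DSP estimate and training learns a correction. Without this the
comb-structured reconstruction gradient holds voiced-frame pitch recovery
near PCC 0.88; with it, held-out recovery is ≈1.0. Pitch estimation from a
magnitude spectrogram is exactly the task classical cepstral trackers solve;
embedding one as a feature is the package's design choice where the
architecture was open.

## ECoG decoders

Input is a frames × rows × cols tensor of z-scored high-gamma envelopes;
rejected electrodes are zero-filled and the validity mask joins as a second
channel. All backbones share one prediction head (same activations as the
encoder). Causal variants guarantee the output at frame t depends only on
inputs ≤ t; the perturbation probe (`causality_probe`) verifies this
exactly.

* **3D ResNet**: per-electrode temporal conv stem, four residual 3D-conv
  blocks (temporal stride 2 each, spatial stride 2 while the grid allows)
  down to 1×1 electrodes and T/16 frames, then four ×2 temporal upsampling
  convs. Causal variants pad left only.
* **3D shifted-window transformer**: 2×2×2 patch partition (48-dim tokens,
  linear embedding to C), stages of (2, 2, 6) layers with window size
  (16, 2, 2) tokens, alternating plain and shifted (half-window) windows,
  2×2×2 patch merging between stages (concatenate → linear to 2C). Attention
  masks live in the shifted frame (the standard construction); in causal
  mode a token may only attend to tokens whose latest source frame is not in
  its future, and the upsampled output is delayed by the merge-induced
  look-ahead so causality holds end to end.
* **LSTM**: LSTM feature extraction over flattened electrodes
  (three layers per trunk, bidirectional when non-causal) + linear, with
  temporal length preserved; the recurrence is a fused operation with an
  explicit backward pass for CPU speed. Two parallel trunks feed the
  shared head — one for frequency-valued parameters, one for
  amplitude-like parameters — so the strong Hz-scale supervision on
  pitch/formants cannot monopolize the features the voice-weight and
  loudness heads depend on. A causal linear bypass from a 4-frame window
  of lagged inputs adds to every pre-activation: when the input mixture is
  near-linear in the underlying controls (as high-gamma envelope
  modulations largely are), the linear path converges in a few hundred
  steps and the recurrent trunks learn the residual structure.

Prediction-head output layers start near zero, so every parameter begins
at its neutral mid-range value; scaled-down schedules optionally decay the
learning rate on a cosine.

## Synthetic data

`simdata` generates word-like trials: ~500 ms at 125 frames/s, alternating
voiced/unvoiced segments (default 3 segments, 70% voiced, jittered per word
by ±1 segment and ±0.15 voiced fraction so different words have genuinely
different voicing structure — without this a shuffled-pairing null model is
spuriously well matched in timing), a smoothed
random-walk pitch contour around a word-level base (140–320 Hz), per-segment
vowel-like formant targets with smooth transitions, broadband bursts in
unvoiced spans, and a raised-cosine loudness envelope. A "word" fixes the
segment targets; trials of the same word differ in contour jitter, so
word-level held-out splits are meaningful. The default split keeps the 7:1
train:test proportion.

Pseudo-ECoG is a linear-lagged mixture: electrode e carries
Σⱼ W[e,j]·z_j(t − lag_e) plus Gaussian noise (default SD 0.1, lags 0–3
frames, 8×8 grid). Parameter series are normalized with dataset-level
statistics so electrodes carry trial-to-trial level differences; a ridge
regression oracle confirms every parameter is decodable at PCC ≥ 0.997
under these conditions, so decoder performance measures the training
pipeline, not an information ceiling. This generator is deliberately not a
biophysical cortex model: passing tests show the estimation machinery
recovers a known generative structure; they do not show that real cortical
dynamics are captured.

## Evaluation conventions

Pitch and formant PCCs are computed on voiced frames (ground-truth voice
weight > 0.5), pooled across held-out trials; voice weight and loudness use
all frames. Decoded spectrograms are synthesized with mean-field noise and
compared to targets carrying a sampled noise realization — with exact
ground-truth parameters this comparison tops out near PCC 0.86, which is the
reference point for decoder spectrogram-PCC numbers. STOI+ is reported
alongside.

## Occlusion analysis

Electrode contribution C_i = mean over test trials of
r(S, Ŝ) − r(S, Ŝ_i), where Ŝ_i is decoded with electrode i zeroed (in the
z-scored input domain, where the decoder consumes it). The noise floor is
the same analysis applied to a model trained on a derangement of the
(ECoG, speech) pairing with identical hyperparameters; reported maps zero
out sub-floor contributions. Contributions are per grid position; anatomical
projection is out of scope.

## Problem sizes used in the test suite

Unit and acceptance tests run at reduced widths chosen for single-CPU
runtime: encoder 48 channels / 4 conv layers, decoders 48 channels, training
a few hundred Adam steps at batch 4–6, 100 trials for auto-encoder recovery
and 300 for decoder recovery, with lr 2e-3 for the scaled-down schedules
(the full-scale default stays at the standard 1e-3). Determinism: every
stochastic component draws from an explicit seed; rerunning any training or
generation call with the same arguments is bitwise reproducible.

## Known limitations

* The synthesizer's prototype filters interpolate 80 samples over 8 kHz;
  formant bandwidths below ~100 Hz are not representable after scaling.
* Gradient checks hold away from piecewise-linear knots; optimizers cross
  knots without issue but second-order methods would not.
* The voice weight and loudness are only weakly identifiable from
  spectrograms alone (scaling loudness down while scaling amplitudes up is
  near-invariant); loudness recovery therefore lags other parameters in the
  auto-encoder. Decoders recover it from the ECoG mixture instead.
* Swin decoder windows larger than the token grid are clamped; extremely
  small grids degenerate to full attention per axis.
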