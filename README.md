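# neurovox

Neural speech decoding with a differentiable formant vocoder: a framework
for translating electrocorticographic (ECoG) recordings of speech cortex
into speech, built for brain–computer-interface research on speech
prostheses.

The package implements:

* a **differentiable source–filter synthesizer** driven by 18 interpretable
  per-frame parameters — pitch f0, six formant centre-frequency/amplitude
  pairs (fᵢ, aᵢ), a broadband unvoice triple (f_û, b_û, a_û), a voice
  weight α ∈ [0, 1] softly mixing the harmonic and noise pathways, and
  loudness L — producing a magnitude spectrogram
  Ŝᵗ(f) = Lᵗ[αᵗVᵗ(f) + (1−αᵗ)Uᵗ(f)] + B(f),
  with learnable speaker parameters (unimodal prototype filters, a
  centre-frequency↔bandwidth relation bᵢ = a(fᵢ−f_θ)+b₀, and a background
  spectrum B): 834 scalars for a female voice profile, 1,090 for male;
* a **speech encoder** forming a speech-to-speech auto-encoder with the
  synthesizer, trained with a multi-scale spectral loss, a STOI+
  intelligibility term, and pitch/formant supervision;
* three interchangeable **ECoG decoders** (3D ResNet, 3D shifted-window
  transformer, LSTM), each in a causal variant (output at frame t depends
  only on input up to t — the real-time prosthesis constraint) and a
  non-causal variant, trained against encoder-reference parameters;
* **occlusion analysis** measuring each electrode's contribution as the
  drop in decoded-spectrogram correlation when it is zeroed, with a
  shuffled-model noise floor;
* an ECoG **preprocessing chain** (common average reference, 70–150 Hz
  high-gamma Hilbert envelope at 125 frames/s, silent-baseline z-scoring);
* a seeded **synthetic-data generator** (word-like parameter trajectories,
  synthesized spectrograms, pseudo-ECoG with a known electrode-to-parameter
  mapping) so the whole pipeline is testable end to end without recordings.

Everything runs on plain numpy/scipy; the neural components train on a
small built-in reverse-mode autodiff engine, so no GPU or deep-learning
framework is required.

## Worked example

`examples/autoencoder_training.py` trains the speech-to-speech auto-encoder
on 42 synthetic word trials and evaluates held-out parameter recovery:

```
$ python examples/autoencoder_training.py
42 training / 6 held-out trials
loss: 3437 -> 17 over 150 steps
held-out recovery (PCC, voiced frames pooled across trials):
  f0        1.000
  f1        0.991
  f2        0.997
  alpha     0.843
reconstruction: mean spectrogram PCC 0.744, STOI+ 0.716
(PCC 1.0 = trajectories recovered exactly; the spectrogram PCC is bounded
below 1 by the stochastic noise excitation of the target)
```

The pitch and first two formant trajectories of unseen trials are recovered
almost exactly from the spectrogram alone; the spectrogram correlation is
capped near 0.86 even for perfect parameters because the target carries a
random noise-excitation realization.

Other examples: `synthesize_word.py` (vocoder + Griffin–Lim audio),
`decode_from_ecog.py` (causal LSTM decoding from pseudo-ECoG, with the
causality probe), `occlusion_analysis.py` (electrode contributions vs the
known generative weights), `preprocess_ecog.py` (raw voltages → z-scored
high-gamma tensors). A thin CLI (`neurovox simulate|synth|train-ae|train-dec|decode|occlude|preproc|run`)
wraps the same entry points.

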