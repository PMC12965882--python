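"""Synthesize a word-like utterance and invert it to audio.

Builds a random speaker and a 500 ms voiced/unvoiced parameter trajectory,
renders the magnitude spectrogram with the differentiable vocoder, and
reconstructs a waveform with Griffin-Lim.
"""

import numpy as np

from neurovox.io import write_wav
from neurovox.simdata import SynthTrialSpec, gen_speaker, gen_word_params
from neurovox.synth import spectrogram_to_waveform, synthesize

spec = SynthTrialSpec()                      # 500 ms, 3 segments, 70% voiced
speaker = gen_speaker(seed=1)
params = gen_word_params(spec, word_seed=4, trial_seed=11)

S = synthesize(params, speaker, seed=0)
print(f"spectrogram: {S.n_frames} frames x {S.n_bins} bins, "
      f"peak magnitude {S.data.max():.2f}")
print(f"voiced fraction: {np.mean(np.asarray(params.alpha) > 0.5):.2f} "
      f"(alpha soft-switches the harmonic vs noise pathway)")
print(f"pitch range: {params.f0.min():.0f}-{params.f0.max():.0f} Hz; "
      f"first formant {params.formant_freq[:, 0].mean():.0f} Hz on average")

wav, errors = spectrogram_to_waveform(S, n_iter=32, seed=0, return_errors=True)
write_wav("word.wav", wav)
print(f"Griffin-Lim: reconstruction error fell {errors[0]:.1f} -> "
      f"{errors[-1]:.1f} over {len(errors)} iterations; wrote word.wav "
      f"({len(wav) / 16000:.2f} s at 16 kHz)")
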