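import numpy as np
import pytest

from neurovox.simdata import (GenerativeMapping, SynthTrialSpec, gen_speaker,
                              gen_word_params, make_dataset)
from neurovox.types import N_FORMANTS, SpeechParams


@pytest.fixture(scope="session")
def speaker():
    return gen_speaker(seed=0)


@pytest.fixture(scope="session")
def toy_params():
    """Deterministic 40-frame trajectory with voiced and unvoiced spans."""
    return gen_word_params(SynthTrialSpec(duration_s=0.32), word_seed=3,
                           trial_seed=7)


def flat_params(T, f0=220.0, amps=(1.0, 0.6, 0.4, 0.3, 0.2, 0.15),
                freqs=(510.0, 1490.0, 2510.0, 3490.0, 4510.0, 5510.0),
                alpha=0.9, loudness=1.0, bb_amp=0.2):
    """Constant-in-time parameters, handy for closed-form checks."""
    return SpeechParams(
        f0=np.full(T, f0),
        formant_freq=np.tile(np.asarray(freqs, dtype=float), (T, 1)),
        formant_amp=np.tile(np.asarray(amps, dtype=float), (T, 1)),
        bb_freq=np.full(T, 3990.0),
        bb_bw=np.full(T, 3000.0),
        bb_amp=np.full(T, bb_amp),
        alpha=np.full(T, float(alpha)),
        loudness=np.full(T, float(loudness)),
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """16 trials on a 2x4 grid with 3 informative electrodes."""
    spec = SynthTrialSpec(grid=(2, 4))
    mapping = GenerativeMapping.informative(grid=(2, 4), n_informative=3,
                                            seed=5, noise_sd=0.05)
    # 8 distinct words so shuffled (mismatched) pairings are genuinely
    # mismatched in voicing structure
    return make_dataset(16, spec, mapping, seed=11, n_words=8)
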