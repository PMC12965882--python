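"""Which electrodes drive decoding? Occlusion analysis with a noise floor.

Only 3 of 8 electrodes carry signal in this synthetic mapping. Occluding
(zeroing) each electrode in turn and measuring the drop in decoded-vs-true
spectrogram correlation recovers them; a "shuffled" model trained on
mismatched (ECoG, speech) pairs provides the significance floor.
"""

import numpy as np

from neurovox.decoders import DecoderConfig, DecoderTrainConfig, train_decoder
from neurovox.occlusion import contribution_map, noise_floor_map
from neurovox.simdata import GenerativeMapping, SynthTrialSpec, make_dataset

grid = (2, 4)
mapping = GenerativeMapping.informative(grid=grid, n_informative=3, seed=5,
                                        noise_sd=0.05)
data = make_dataset(48, SynthTrialSpec(grid=grid), mapping, seed=3)

cfg = DecoderConfig(backbone="lstm", causal=True, channels=24, head_hidden=16)
tcfg = DecoderTrainConfig(steps=120, batch_size=6, lr=2e-3)
dec, _ = train_decoder(data.train, data.speaker, cfg, tcfg, seed=1)

cm = contribution_map(dec, data.speaker, data.test, seed=0)
floor = noise_floor_map(data.train, data.test, data.speaker, cfg, tcfg, seed=2)
cm.noise_floor = floor.contrib

strength = mapping.electrode_strength().reshape(grid)
print("ground-truth signal weight per electrode:\n", np.round(strength, 2))
print("occlusion contribution (delta spectrogram PCC):\n",
      np.round(cm.contrib, 4))
print("shuffled-model noise floor:\n", np.round(floor.contrib, 4))
print("significant (floor-thresholded) contributions:\n",
      np.round(cm.significant(), 4))
print("-> electrodes with nonzero generative weight should carry the "
      "significant contributions; pure-noise electrodes sit at the floor")
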