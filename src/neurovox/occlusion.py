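"""Electrode contribution analysis by occlusion.

The contribution of electrode i is the mean drop, over test trials, of the
Pearson correlation between decoded and ground-truth spectrograms when that
electrode's (z-scored) input is set to zero:

    C_i = Mean{ r(S, S_hat) - r(S, S_hat_i) }

A matched noise floor comes from a "shuffled" model trained on deliberately
mismatched (ECoG, speech) pairings — a derangement of the trials — analysed
with exactly the same occlusion procedure and hyperparameters; contributions
below the floor are zeroed in significance-filtered reports. Contributions
are reported per electrode-grid position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import synthesize
from .types import ECoGTensor, SpeechParams

__all__ = ["ContributionMap", "spectrogram_pcc", "electrode_contribution",
           "contribution_map", "noise_floor_map", "derangement"]


@dataclass
class ContributionMap:
    contrib: np.ndarray          # (rows, cols) mean delta-PCC
    n_trials: int
    noise_floor: np.ndarray = None

    def significant(self) -> np.ndarray:
        """Contributions with sub-floor entries zeroed."""
        if self.noise_floor is None:
            raise ValueError("no noise floor attached")
        return np.where(self.contrib > self.noise_floor, self.contrib, 0.0)


def spectrogram_pcc(S_hat, S) -> float:
    """Pearson correlation over all time-frequency cells."""
    a = (S_hat.data if hasattr(S_hat, "data") else np.asarray(S_hat)).ravel()
    b = (S.data if hasattr(S, "data") else np.asarray(S)).ravel()
    if a.shape != b.shape:
        raise ValueError("spectrogram shapes disagree")
    if a.std() < 1e-15 or b.std() < 1e-15:
        raise ValueError("zero-variance spectrogram has no defined PCC")
    return float(np.corrcoef(a, b)[0, 1])


def _occlude(ecog: ECoGTensor, electrode) -> ECoGTensor:
    r, c = electrode
    vals = ecog.values.copy()
    vals[:, r, c] = 0.0
    return ECoGTensor(vals, frame_rate=ecog.frame_rate,
                      valid_mask=ecog.valid_mask)


def _decoded_spec(decoder, speaker, ecog, seed=None):
    pred = decoder(ecog)
    # expected-noise (mean-field) synthesis: deterministic decoded output
    return synthesize(SpeechParams.from_array(pred.as_array()), speaker,
                      seed=None)


def electrode_contribution(decoder, speaker, test_set, electrode,
                           seed: int = 0) -> float:
    """Mean over test trials of intact-PCC minus occluded-PCC for one
    electrode; positive values mean the electrode helps decoding."""
    if len(test_set) == 0:
        raise ValueError("empty test set")
    grid = test_set[0]["ecog"].grid_shape
    r, c = electrode
    if not (0 <= r < grid[0] and 0 <= c < grid[1]):
        raise ValueError("electrode outside the grid")
    deltas = []
    for k, tr in enumerate(test_set):
        s_int = _decoded_spec(decoder, speaker, tr["ecog"], seed + k)
        s_occ = _decoded_spec(decoder, speaker, _occlude(tr["ecog"], electrode),
                              seed + k)
        S = tr["spectrogram"]
        deltas.append(spectrogram_pcc(s_int, S) - spectrogram_pcc(s_occ, S))
    return float(np.mean(deltas))


def contribution_map(decoder, speaker, test_set, seed: int = 0) -> ContributionMap:
    """Occlusion contribution for every grid position (mask-respecting:
    already-zero rejected electrodes get an exact 0)."""
    if len(test_set) == 0:
        raise ValueError("empty test set")
    grid = test_set[0]["ecog"].grid_shape
    mask = test_set[0]["ecog"].valid_mask
    # cache intact decodes once; occlusion reuses the same noise seeds
    intact = [spectrogram_pcc(_decoded_spec(decoder, speaker, tr["ecog"], seed + k),
                              tr["spectrogram"])
              for k, tr in enumerate(test_set)]
    contrib = np.zeros(grid)
    for r in range(grid[0]):
        for c in range(grid[1]):
            if not mask[r, c]:
                continue
            if all(np.all(tr["ecog"].values[:, r, c] == 0) for tr in test_set):
                continue      # zero-variance input: occlusion changes nothing
            deltas = []
            for k, tr in enumerate(test_set):
                s_occ = _decoded_spec(decoder, speaker,
                                      _occlude(tr["ecog"], (r, c)), seed + k)
                deltas.append(intact[k] - spectrogram_pcc(s_occ, tr["spectrogram"]))
            contrib[r, c] = np.mean(deltas)
    return ContributionMap(contrib=contrib, n_trials=len(test_set))


def derangement(n: int, rng) -> np.ndarray:
    """Random permutation of range(n) with no fixed point."""
    if n < 2:
        raise ValueError("need at least two trials to mismatch pairs")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def noise_floor_map(train_set, test_set, speaker, decoder_config=None,
                    train_config=None, seed: int = 0) -> ContributionMap:
    """Contribution map of a shuffled model trained on mismatched pairs.

    The shuffled model shares hyperparameters and training schedule with
    the real model; only the (ECoG, speech) pairing is deranged. Its
    occlusion map estimates the contribution noise level.
    """
    from .decoders import train_decoder
    rng = np.random.default_rng(seed)
    perm = derangement(len(train_set), rng)
    shuffled = []
    for i, j in enumerate(perm):
        tr = dict(train_set[i])
        other = train_set[j]
        L = min(tr["ecog"].n_frames, other["spectrogram"].n_frames)
        shuffled.append({
            "ecog": ECoGTensor(tr["ecog"].values[:L],
                               valid_mask=tr["ecog"].valid_mask),
            "spectrogram": other["spectrogram"],
            "guidance": other["guidance"],
            "f0": other["f0"], "formants": other["formants"],
        })
    dec, _ = train_decoder(shuffled, speaker, decoder_config, train_config,
                           seed=seed)
    cm = contribution_map(dec, speaker, test_set, seed=seed)
    return ContributionMap(contrib=cm.contrib, n_trials=cm.n_trials)
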