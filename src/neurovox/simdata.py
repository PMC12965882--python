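"""Seeded synthetic data: word-like speech-parameter trajectories, their
synthesized spectrograms, and pseudo-ECoG with a known generative mapping.

Trials emulate single-word productions of about 500 ms at 125 frames/s on an
8x8 electrode grid. A "word" is a trial archetype: segment targets (vowel
formant patterns, broadband bursts) are drawn per word, and each trial adds
per-trial contour jitter, so word-level splits are meaningful. Pseudo-ECoG
is a linear-lagged mixture of the z-scored parameter series plus Gaussian
noise — not a biophysical model, but one whose ground-truth electrode
contributions and recoverable parameters are known exactly, which is what
the decoder, occlusion and recovery tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .synth import M_PROTO, N_FORMANTS, PROFILES, SpeakerParams, synthesize
from .types import BB_BW_MIN, F_MAX, FRAME_RATE, ECoGTensor, SpeechParams

__all__ = ["SynthTrialSpec", "GenerativeMapping", "gen_word_params",
           "gen_speaker", "gen_pseudo_ecog", "make_dataset", "SimDataset"]

#: per-segment formant target ranges (Hz), kept inside the encoder's
#: frequency search ranges
_FORMANT_TARGETS = [(300, 900), (1000, 2500), (1500, 3800), (2500, 4800),
                    (3500, 6500), (4500, 7500)]
_AMP_BASE = np.array([1.0, 0.6, 0.4, 0.25, 0.15, 0.1])


@dataclass
class SynthTrialSpec:
    """Conditions of one synthetic word-production trial."""

    duration_s: float = 0.5
    n_segments: int = 3            # voiced/unvoiced alternation, starts voiced
    voiced_fraction: float = 0.7
    f0_range: tuple = (140.0, 320.0)
    grid: tuple = (8, 8)
    profile: str = "female"

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * FRAME_RATE))


def _segment_lengths(T, n_segments, voiced_fraction):
    n_voiced = (n_segments + 1) // 2
    n_unvoiced = n_segments - n_voiced
    Tv = int(round(T * voiced_fraction))
    Tu = T - Tv
    lens = []
    for i in range(n_segments):
        if i % 2 == 0:
            lens.append(Tv // n_voiced)
        else:
            lens.append(Tu // max(n_unvoiced, 1))
    lens[-1] += T - sum(lens)
    return lens


def gen_word_params(spec: SynthTrialSpec, word_seed: int = 0,
                    trial_seed: int = 0) -> SpeechParams:
    """One trial's 18-parameter trajectories.

    Segment targets come from ``word_seed`` (shared by all trials of the
    same word); the pitch walk, amplitude jitter and timing noise come from
    ``trial_seed``. Output satisfies all parameter invariants.
    """
    word_rng = np.random.default_rng(word_seed)
    trial_rng = np.random.default_rng(trial_seed)
    T = spec.n_frames
    # words differ in voicing structure: per-word jitter of the voiced
    # fraction and segment count around the configured values
    vf = float(np.clip(spec.voiced_fraction + word_rng.uniform(-0.15, 0.15),
                       0.3, 0.9))
    n_seg = max(1, spec.n_segments + int(word_rng.integers(-1, 2)))
    lens = _segment_lengths(T, n_seg, vf)
    bounds = np.concatenate([[0], np.cumsum(lens)])
    voiced_mask = np.zeros(T)
    for i in range(n_seg):
        if i % 2 == 0:
            voiced_mask[bounds[i]:bounds[i + 1]] = 1.0

    lo0, hi0 = spec.f0_range
    base = word_rng.uniform(lo0 + 30, hi0 - 30)
    walk = np.cumsum(trial_rng.normal(0, 2.5, T))
    f0 = np.clip(base + gaussian_filter1d(walk, 3), lo0, hi0)

    ff = np.zeros((T, N_FORMANTS))
    for i, (lo, hi) in enumerate(_FORMANT_TARGETS):
        targets = word_rng.uniform(lo, hi, n_seg)
        series = np.repeat(targets, lens)
        jitter = gaussian_filter1d(trial_rng.normal(0, 0.01 * (hi - lo), T), 4)
        ff[:, i] = np.clip(gaussian_filter1d(series, 4) + jitter, lo, hi)
    ff.sort(axis=1)   # formants stay ordered after smoothing/jitter

    fa = np.zeros((T, N_FORMANTS))
    for i in range(N_FORMANTS):
        seg_amp = _AMP_BASE[i] * word_rng.lognormal(0, 0.25, n_seg)
        fa[:, i] = gaussian_filter1d(np.repeat(seg_amp, lens), 4)

    bb_f = gaussian_filter1d(
        np.repeat(word_rng.uniform(2500, 6000, n_seg), lens), 4)
    bb_b = gaussian_filter1d(
        np.repeat(word_rng.uniform(2600, 5000, n_seg), lens), 4)
    bb_b = np.clip(bb_b, BB_BW_MIN + 100, F_MAX)
    bb_a = gaussian_filter1d(np.where(voiced_mask > 0.5, 0.02, 0.5), 3)

    alpha = np.clip(gaussian_filter1d(0.05 + 0.9 * voiced_mask, 2), 0.0, 1.0)

    ramp = int(round(0.05 * FRAME_RATE))
    env = np.ones(T)
    env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[-ramp:] = env[:ramp][::-1]
    loud = env * (0.8 + 0.3 * word_rng.random()) \
        * np.exp(gaussian_filter1d(trial_rng.normal(0, 0.05, T), 6))

    return SpeechParams(f0=f0, formant_freq=ff, formant_amp=fa,
                        bb_freq=np.clip(bb_f, 0, F_MAX), bb_bw=bb_b,
                        bb_amp=np.clip(bb_a, 0, None), alpha=alpha,
                        loudness=np.clip(loud, 0, None)).validate()


def gen_speaker(seed: int = 0, profile: str = "female") -> SpeakerParams:
    """Random speaker: unimodal prototype filters with randomized peak
    positions/widths, plausible bandwidth relations, low background."""
    rng = np.random.default_rng(seed)
    K = PROFILES[profile]
    grid = np.linspace(0.0, F_MAX, M_PROTO)
    protos = []
    for _ in range(N_FORMANTS + 1):
        c = rng.uniform(1000, 6000)
        w = rng.uniform(500, 1500)
        g = np.exp(-0.5 * ((grid - c) / w) ** 2)
        protos.append(g / g.max())
    bw = np.column_stack([
        rng.uniform(400, 600, N_FORMANTS),
        rng.uniform(0.04, 0.10, N_FORMANTS),
        rng.uniform(60, 120, N_FORMANTS),
    ])
    background = rng.uniform(5e-4, 2e-3) * (1 + 0.2 * rng.standard_normal(K))
    background = np.clip(gaussian_filter1d(background, 8), 1e-5, None)
    return SpeakerParams.from_components(np.array(protos), bw, background)


@dataclass
class GenerativeMapping:
    """Linear-lagged electrode model: ``e_i(t) = sum_j W[i,j] z_j(t - lag_i)
    + noise``, with ``z`` the z-scored parameter series."""

    weights: np.ndarray          # (n_electrodes, 18)
    lags: np.ndarray             # (n_electrodes,) frames, >= 0
    noise_sd: float = 0.1

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.lags = np.asarray(self.lags, dtype=int)
        if np.all(self.weights == 0):
            raise ValueError("mapping needs at least one nonzero weight")
        if np.any(self.lags < 0):
            raise ValueError("lags must be nonnegative (causal ground truth)")

    @property
    def n_electrodes(self) -> int:
        return self.weights.shape[0]

    def electrode_strength(self) -> np.ndarray:
        """Per-electrode signal weight (L2 norm of its mixing row)."""
        return np.linalg.norm(self.weights, axis=1)

    @classmethod
    def dense(cls, grid=(8, 8), seed: int = 0, noise_sd: float = 0.1,
              max_lag: int = 3, sparsity: float = 0.25) -> "GenerativeMapping":
        """Every electrode mixes a sparse random subset of parameters."""
        rng = np.random.default_rng(seed)
        n = grid[0] * grid[1]
        W = rng.normal(0, 1.0, (n, 18)) * (rng.random((n, 18)) < sparsity)
        for i in np.where(np.all(W == 0, axis=1))[0]:
            W[i, rng.integers(18)] = rng.normal(0, 1.0)
        lags = rng.integers(0, max_lag + 1, n)
        return cls(W, lags, noise_sd)

    @classmethod
    def informative(cls, grid=(2, 4), n_informative: int = 3, seed: int = 0,
                    noise_sd: float = 0.1, max_lag: int = 2) -> "GenerativeMapping":
        """Only ``n_informative`` electrodes carry signal; the rest are
        pure noise. Used by the occlusion oracles."""
        rng = np.random.default_rng(seed)
        n = grid[0] * grid[1]
        W = np.zeros((n, 18))
        chosen = rng.choice(n, size=n_informative, replace=False)
        strengths = np.linspace(1.0, 2.0, n_informative)
        for e, s in zip(chosen, strengths):
            picks = rng.choice(18, size=4, replace=False)
            W[e, picks] = s * rng.normal(0, 1.0, 4)
            W[e] *= s / max(np.linalg.norm(W[e]), 1e-9)
        lags = rng.integers(0, max_lag + 1, n)
        return cls(W, lags, noise_sd)


def gen_pseudo_ecog(params: SpeechParams, mapping: GenerativeMapping,
                    seed: int = 0, grid=(8, 8), stats=None) -> ECoGTensor:
    """Pseudo-ECoG from a known linear-lagged mixing of the parameters.

    ``stats=(mu, sd)`` are the normalization statistics for the 18
    parameter series; pass dataset-level (speaker-level) statistics so the
    electrodes carry trial-to-trial level differences — the default falls
    back to per-trial statistics.
    """
    arr = params.as_array()                       # (T, 18)
    mu, sd = stats if stats is not None else (arr.mean(axis=0), arr.std(axis=0))
    z = (arr - mu) / np.where(sd < 1e-9, 1.0, sd)
    z[:, sd < 1e-9] = 0.0
    T = z.shape[0]
    n = mapping.n_electrodes
    if n != grid[0] * grid[1]:
        raise ValueError("mapping size does not match the electrode grid")
    rng = np.random.default_rng(seed)
    E = np.zeros((T, n))
    for e in range(n):
        lag = mapping.lags[e]
        zl = np.zeros_like(z)
        zl[lag:] = z[:T - lag] if lag else z
        E[:, e] = zl @ mapping.weights[e]
    E += mapping.noise_sd * rng.standard_normal(E.shape)
    return ECoGTensor(E.reshape(T, grid[0], grid[1]))


@dataclass
class SimDataset:
    trials: list
    train_idx: np.ndarray
    test_idx: np.ndarray
    speaker: SpeakerParams
    mapping: GenerativeMapping
    manifest: dict

    @property
    def train(self):
        return [self.trials[i] for i in self.train_idx]

    @property
    def test(self):
        return [self.trials[i] for i in self.test_idx]


def make_dataset(n_trials: int, spec: SynthTrialSpec = None,
                 mapping: GenerativeMapping = None, seed: int = 0,
                 n_words: int = None) -> SimDataset:
    """Paired (SpeechParams, Spectrogram, ECoGTensor) trials + manifest.

    The train/test split keeps the 7:1 proportion of the 350/50 protocol;
    ``guidance`` in each trial is the ground-truth parameter trajectory (it
    plays the role a trained speech encoder's reference plays for real
    data). Fully deterministic: regeneration from the manifest is bitwise
    identical.
    """
    if n_trials < 2:
        raise ValueError("need at least two trials")
    spec = spec or SynthTrialSpec()
    mapping = mapping or GenerativeMapping.dense(spec.grid, seed=seed + 1)
    n_words = n_words or max(1, n_trials // 8)
    root = np.random.default_rng(seed)
    speaker_seed = int(root.integers(2 ** 31))
    word_seeds = [int(root.integers(2 ** 31)) for _ in range(n_words)]
    trial_seeds = [int(root.integers(2 ** 31)) for _ in range(n_trials)]
    speaker = gen_speaker(speaker_seed, spec.profile)
    all_params = [gen_word_params(spec, word_seeds[i % n_words], trial_seeds[i])
                  for i in range(n_trials)]
    pooled = np.concatenate([p.as_array() for p in all_params], axis=0)
    stats = (pooled.mean(axis=0), pooled.std(axis=0))
    trials = []
    for i in range(n_trials):
        word = i % n_words
        p = all_params[i]
        S = synthesize(p, speaker, seed=trial_seeds[i] + 1)
        ecog = gen_pseudo_ecog(p, mapping, seed=trial_seeds[i] + 2,
                               grid=spec.grid, stats=stats)
        trials.append({
            "params": p, "spectrogram": S, "ecog": ecog, "guidance": p,
            "f0": p.f0, "formants": p.formant_freq[:, :4],
            "voiced": p.alpha > 0.5,
            "word_id": word, "trial_seed": trial_seeds[i],
        })
    n_test = max(1, int(round(n_trials / 8)))
    perm = root.permutation(n_trials)
    test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
    manifest = {
        "seed": seed, "n_trials": n_trials, "n_words": n_words,
        "spec": asdict(spec), "speaker_seed": speaker_seed,
        "word_seeds": word_seeds, "trial_seeds": trial_seeds,
        "noise_sd": mapping.noise_sd,
        "train_idx": train_idx.tolist(), "test_idx": test_idx.tolist(),
    }
    return SimDataset(trials, train_idx, test_idx, speaker, mapping, manifest)
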