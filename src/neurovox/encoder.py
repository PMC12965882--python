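"""Speech encoder: spectrogram -> 18 per-frame speech parameters.

Together with the differentiable synthesizer this forms the speech-to-speech
auto-encoder used to learn speaker parameters and to produce reference
parameter trajectories for ECoG-decoder training.

Architecture: temporal convolutions over the linear-scale spectrogram
followed by per-frame channel MLP heads. The pitch head additionally
consumes features from a Mel-scale branch (pitch harmonics are more evenly
spaced there). Frequency-valued outputs pass through a sigmoid and are
de-normalized from [0, 1] to configured [f_min, f_max] ranges; amplitudes
and loudness use softplus; the voice weight uses a sigmoid; the broadband
bandwidth maps onto (2000, f_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, as_tensor, concat, sigmoid, softplus
from .losses import LossWeights, autoencoder_total, mel_filterbank
from .nn import MLP, Adam, Conv1d, LayerNorm, Module
from .synth import PROFILES, SpeakerParams, synthesize
from .types import BB_BW_MIN, F_MAX, N_FORMANTS, SpeechParams, Spectrogram

#: frequency search ranges (Hz) for each frequency-valued parameter
DEFAULT_RANGES = {
    "f0": (50.0, 400.0),
    "f1": (200.0, 1000.0),
    "f2": (500.0, 3000.0),
    "f3": (1200.0, 4000.0),
    "f4": (2000.0, 5000.0),
    "f5": (3000.0, 7000.0),
    "f6": (4000.0, 8000.0),
    "f_bb": (1000.0, 8000.0),
    "b_bb": (BB_BW_MIN, F_MAX),
}


def denormalize_frequency(u, frange):
    """Map a unit-interval activation to ``[f_min, f_max]`` Hz."""
    lo, hi = frange
    if not (0.0 <= lo < hi):
        raise ValueError("invalid frequency range")
    if not isinstance(u, Tensor):
        ua = np.asarray(u, dtype=np.float64)
        if np.any(ua < 0) or np.any(ua > 1):
            raise ValueError("activation outside [0, 1]")
    return as_tensor(u) * (hi - lo) + lo


@dataclass
class EncoderConfig:
    n_conv: int = 5
    channels: int = 64
    kernel: int = 5
    mel_channels: int = 32
    n_mels: int = 80
    mlp_hidden: int = 32
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))

    def scaled(self, width_factor: float) -> "EncoderConfig":
        return replace(self, channels=max(8, int(self.channels * width_factor)),
                       mel_channels=max(4, int(self.mel_channels * width_factor)),
                       mlp_hidden=max(8, int(self.mlp_hidden * width_factor)))


class SpeechEncoder(Module):
    def __init__(self, n_bins: int, config: EncoderConfig = None, seed: int = 0):
        cfg = config or EncoderConfig()
        self.config = cfg
        self.n_bins = n_bins
        self.trained = False        # metadata: flips after train_autoencoder
        rng = np.random.default_rng(seed)
        w = cfg.channels
        self.convs = [Conv1d(n_bins, w, cfg.kernel, rng)]
        self.convs += [Conv1d(w, w, cfg.kernel, rng) for _ in range(cfg.n_conv - 1)]
        self.norm = LayerNorm(w)
        self.mel_fb = mel_filterbank(n_bins, n_mels=cfg.n_mels)
        self.mel_conv = Conv1d(cfg.n_mels, cfg.mel_channels, cfg.kernel, rng)
        self.mel_conv2 = Conv1d(cfg.mel_channels, cfg.mel_channels,
                                cfg.kernel, rng)
        # pitch also reads the fundamental region of the linear spectrogram
        # and a cepstral band whose quefrencies cover the f0 search range
        self.low_bins = max(8, int(round(600.0 / (F_MAX / n_bins))))
        self.low_conv = Conv1d(self.low_bins, cfg.mel_channels, cfg.kernel, rng)
        lo, hi = cfg.ranges["f0"]
        q_lo = max(2, int(np.floor(2 * F_MAX / hi)))
        q_hi = min(n_bins - 1, int(np.ceil(2 * F_MAX / lo)))
        k = np.arange(n_bins)
        q = np.arange(q_lo, q_hi + 1)
        self.cep_mat = np.cos(np.pi * np.outer(k + 0.5, q) / n_bins) / n_bins
        self.cep_conv = Conv1d(len(q), cfg.mel_channels, cfg.kernel, rng)
        self.cep_q = q
        h = cfg.mlp_hidden
        # +2: explicit cepstral-peak pitch estimate and its confidence;
        # zero-initialized output layer so the head starts exactly at the
        # cepstral estimate (the sigmoid bias) and learns a correction
        self.head_f0 = MLP(w + 3 * cfg.mel_channels + 2, h, 1, rng)
        self.head_f0.fc2.weight.data[:] = 0.0
        self.head_ff = MLP(w, h, N_FORMANTS, rng)
        self.head_fa = MLP(w, h, N_FORMANTS, rng)
        self.head_bb = MLP(w, h, 3, rng)
        self.head_alpha = MLP(w, h, 1, rng)
        self.head_loud = MLP(w, h, 1, rng)

    def __call__(self, spec) -> SpeechParams:
        return self.encode(spec)

    def _cepstral_pitch(self, cep: np.ndarray) -> np.ndarray:
        """Per-frame (T, 2) pitch feature from the cepstrum of the input:
        normalized cepstral-peak pitch (parabolic sub-sample refinement)
        and the peak prominence as a confidence value."""
        lo, hi = self.config.ranges["f0"]
        T, nq = cep.shape
        i = np.argmax(cep, axis=1)
        im = np.clip(i, 1, nq - 2)
        c0, c1, c2 = (cep[np.arange(T), im - 1], cep[np.arange(T), im],
                      cep[np.arange(T), im + 1])
        denom = c0 - 2 * c1 + c2
        frac = np.where(np.abs(denom) > 1e-12,
                        0.5 * (c0 - c2) / np.where(denom == 0, 1, denom), 0.0)
        q_star = self.cep_q[im] + np.clip(frac, -0.5, 0.5)
        f0_est = 2.0 * F_MAX / q_star
        # pitch continuity: a short median filter removes octave glitches
        from scipy.signal import medfilt
        if T >= 5:
            f0_med = medfilt(f0_est, 5)
            glitch = np.abs(f0_est - f0_med) > 0.2 * f0_med
            f0_est = np.where(glitch, f0_med, f0_est)
        conf = np.tanh((c1 - cep.mean(axis=1)) / (cep.std(axis=1) + 1e-9) / 3.0)
        return np.column_stack([(np.clip(f0_est, lo, hi) - lo) / (hi - lo),
                                conf])

    def encode(self, spec) -> SpeechParams:
        """Per-frame speech parameters; frame count matches the input."""
        S = spec.values if isinstance(spec, Spectrogram) else spec
        S = as_tensor(S)
        if S.shape[1] != self.n_bins:
            raise ValueError("spectrogram bin count does not match encoder")
        r = self.config.ranges
        # standardize the log spectrogram with detached per-trial stats
        xl = (S + 1e-3).log()
        m, sd = float(np.mean(xl.data)), float(np.std(xl.data)) + 1e-6
        x = (xl - m) * (1.0 / sd)
        feat = x
        for conv in self.convs:
            feat = conv(feat).tanh()
        feat = self.norm(feat)
        mel = ((S @ self.mel_fb) + 1e-3).log()
        mel = (mel - float(np.mean(mel.data))) * (1.0 / (float(np.std(mel.data)) + 1e-6))
        mel_feat = self.mel_conv2(self.mel_conv(mel).tanh()).tanh()
        low = x[:, :self.low_bins]
        low = (low - float(np.mean(low.data))) * (1.0 / (float(np.std(low.data)) + 1e-6))
        low_feat = self.low_conv(low).tanh()
        cep = x @ self.cep_mat
        cep = (cep - float(np.mean(cep.data))) * (1.0 / (float(np.std(cep.data)) + 1e-6))
        cep_feat = self.cep_conv(cep).tanh()
        pitch_est = self._cepstral_pitch(cep.data)
        T = S.shape[0]

        # the sigmoid is biased by the cepstral pitch estimate's logit, so
        # the head starts at the DSP estimate and learns a correction
        u_est = np.clip(pitch_est[:, 0], 1e-4, 1 - 1e-4)
        logit_est = np.log(u_est / (1 - u_est))
        h_f0 = self.head_f0(concat([feat, mel_feat, low_feat,
                                    cep_feat, Tensor(pitch_est)], axis=1))
        f0 = denormalize_frequency(
            sigmoid(h_f0.reshape(T) + logit_est).reshape(T), r["f0"])
        ff_u = sigmoid(self.head_ff(feat))
        ff_cols = [denormalize_frequency(ff_u[:, i], r[f"f{i + 1}"])
                   for i in range(N_FORMANTS)]
        from .autodiff import stack
        ff = stack(ff_cols, axis=1)
        fa = softplus(self.head_fa(feat))
        bb = self.head_bb(feat)
        bb_f = denormalize_frequency(sigmoid(bb[:, 0]), r["f_bb"])
        lo, hi = r["b_bb"]
        bb_b = sigmoid(bb[:, 1]) * (hi - lo) + (lo + 1e-6)   # open at 2000 Hz
        bb_a = softplus(bb[:, 2])
        alpha = sigmoid(self.head_alpha(feat)).reshape(T)
        loud = softplus(self.head_loud(feat)).reshape(T)
        return SpeechParams(f0=f0, formant_freq=ff, formant_amp=fa,
                            bb_freq=bb_f, bb_bw=bb_b, bb_amp=bb_a,
                            alpha=alpha, loudness=loud)


@dataclass
class TrainConfig:
    steps: int = 1000
    batch_size: int = 8
    lr: float = 1e-3
    lr_final: float = None      # cosine-decay target; None = constant lr
    profile: str = "female"
    patience: int = 0           # 0 disables plateau early stopping
    weights: LossWeights = field(default_factory=LossWeights)


def train_autoencoder(trials, config: TrainConfig = None,
                      encoder_config: EncoderConfig = None, seed: int = 0):
    """Pre-train the speech encoder and speaker parameters.

    ``trials`` is a sequence of dicts with keys ``spectrogram``
    (:class:`Spectrogram`), ``f0`` ((T,) Hz) and ``formants`` ((T, >=4) Hz)
    supervision series (ground truth for synthetic data, or estimates from
    :mod:`neurovox.estimators` for recorded audio).

    Returns ``(encoder, speaker_params, history)`` where ``history`` is the
    per-step loss curve. Deterministic given ``seed``.
    """
    if len(trials) < 1:
        raise ValueError("need at least one training trial")
    cfg = config or TrainConfig()
    if cfg.profile not in PROFILES:
        raise ValueError(f"unknown profile {cfg.profile!r}")
    rng = np.random.default_rng(seed)
    n_bins = trials[0]["spectrogram"].n_bins
    enc = SpeechEncoder(n_bins, encoder_config, seed=int(rng.integers(2 ** 31)))
    speaker = SpeakerParams.default(cfg.profile, seed=int(rng.integers(2 ** 31)))
    opt = Adam(enc.parameters() + speaker.parameters(), lr=cfg.lr)
    history = []
    best, since_best = np.inf, 0
    for step in range(cfg.steps):
        if cfg.lr_final is not None:
            frac = 0.5 * (1 + np.cos(np.pi * step / max(cfg.steps - 1, 1)))
            opt.lr = cfg.lr_final + (cfg.lr - cfg.lr_final) * frac
        idx = rng.choice(len(trials), size=min(cfg.batch_size, len(trials)),
                         replace=False)
        opt.zero_grad()
        total = None
        for i in idx:
            tr = trials[i]
            S = tr["spectrogram"]
            pred = enc.encode(S)
            # expected-noise synthesis: deterministic reconstruction whose
            # gradients are not polluted by a fresh noise realization
            S_hat = synthesize(pred, speaker, seed=None)
            loss = autoencoder_total(S_hat.values, S.values, pred,
                                     tr["f0"], np.asarray(tr["formants"])[:, :4],
                                     cfg.weights, tr.get("voiced"))
            total = loss if total is None else total + loss
        total = total * (1.0 / len(idx))
        val = total.item()
        if not np.isfinite(val):
            raise RuntimeError(f"auto-encoder training diverged at step {step} "
                               f"(loss={val})")
        total.backward()
        opt.step()
        history.append(val)
        if cfg.patience:
            if val < best - 1e-6:
                best, since_best = val, 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    enc.trained = True
    return enc, speaker, history
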