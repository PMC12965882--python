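"""ECoG-to-speech-parameter decoders: 3D ResNet, 3D shifted-window
transformer, and LSTM backbones, each in causal and non-causal variants.

All backbones consume a ``frames x rows x cols`` tensor of z-scored
high-gamma envelopes (rejected electrodes are zero-filled and their mask is
concatenated as a second input channel) and emit 18 speech parameters per
frame through a shared prediction head with the same output activations as
the speech encoder. In a causal variant the output at frame ``t`` is a
function of input frames ``<= t`` only — the property a real-time speech
prosthesis requires — which every temporal operator here honours by
construction (left-only padding, unidirectional recurrence, temporal
attention masking).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, as_tensor, concat, sigmoid, softplus, stack
from .encoder import DEFAULT_RANGES, denormalize_frequency
from .losses import LossWeights, decoder_total
from .nn import (MLP, Adam, Conv1d, Conv3d, LayerNorm, Linear, LSTM, Module,
                 UpsampleConv1d)
from .types import BB_BW_MIN, F_MAX, N_FORMANTS, ECoGTensor, SpeechParams

__all__ = ["DecoderConfig", "ResNet3dDecoder", "Swin3dDecoder", "LSTMDecoder",
           "make_decoder", "resnet_decode", "swin_decode", "lstm_decode",
           "train_decoder", "causality_probe"]


@dataclass
class DecoderConfig:
    backbone: str = "resnet3d"          # resnet3d | swin3d | lstm
    causal: bool = True
    channels: int = 128                 # base feature width C
    n_res_blocks: int = 4
    swin_layers: tuple = (2, 2, 6)      # (2, 2, 6, 2) for hybrid-density grids
    window: tuple = (16, 2, 2)          # (P, M, M) window in tokens
    patch: tuple = (2, 2, 2)
    patch_dim: int = 48                 # token feature size after partition
    n_heads: int = 4
    lstm_layers: int = 3
    head_hidden: int = 32
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))

    def toy(self) -> "DecoderConfig":
        """Reduced widths for CPU-scale experiments."""
        return replace(self, channels=32, patch_dim=16, n_heads=2,
                       head_hidden=16)


class ParamHead(Module):
    """Shared prediction head: temporal conv + per-group channel MLPs.

    Reused by every backbone so all decoders emit speech parameters with
    identical range guarantees (sigmoid + de-normalization for frequencies,
    softplus positivity for amplitudes/loudness, sigmoid voice weight,
    broadband bandwidth mapped onto (2000, f_max]).
    """

    def __init__(self, d_in: int, hidden: int, ranges: dict, rng,
                 causal: bool = False, two_stream: bool = False):
        self.ranges = dict(ranges)
        self.conv = Conv1d(d_in, hidden, 3, rng, causal=causal)
        if two_stream:
            self.conv_amp = Conv1d(d_in, hidden, 3, rng, causal=causal)
        self.head_f0 = MLP(hidden, hidden, 1, rng)
        self.head_ff = MLP(hidden, hidden, N_FORMANTS, rng)
        self.head_fa = MLP(hidden, hidden, N_FORMANTS, rng)
        self.head_bb = MLP(hidden, hidden, 3, rng)
        self.head_alpha = MLP(hidden, hidden, 1, rng)
        self.head_loud = MLP(hidden, hidden, 1, rng)
        # near-zero output layers: every parameter starts close to its
        # neutral mid-range value instead of random error the trunk must
        # unlearn (small nonzero scale keeps outputs input-dependent)
        for head in (self.head_f0, self.head_ff, self.head_fa, self.head_bb,
                     self.head_alpha, self.head_loud):
            head.fc2.weight.data *= 1e-2

    def __call__(self, feat: Tensor, feat_amp: Tensor = None,
                 bias: Tensor = None) -> SpeechParams:
        """``feat_amp`` optionally provides a second feature stream for the
        amplitude-like heads (voice weight, loudness, amplitudes, broadband);
        backbones with a single trunk pass one stream for both.
        ``bias`` (T, 18) adds pre-activation logits per parameter (e.g. a
        linear bypass from the input), ordered f0, f1-6, a1-6, f_bb, b_bb,
        a_bb, alpha, loudness."""
        r = self.ranges
        feat = self.conv(feat).tanh()
        amp = feat if feat_amp is None else self.conv_amp(feat_amp).tanh()
        T = feat.shape[0]
        h_f0 = self.head_f0(feat)
        h_ff = self.head_ff(feat)
        h_fa = self.head_fa(amp)
        h_bb = self.head_bb(amp)
        h_al = self.head_alpha(amp)
        h_ld = self.head_loud(amp)
        if bias is not None:
            h_f0 = h_f0 + bias[:, 0:1]
            h_ff = h_ff + bias[:, 1:7]
            h_fa = h_fa + bias[:, 7:13]
            h_bb = h_bb + bias[:, 13:16]
            h_al = h_al + bias[:, 16:17]
            h_ld = h_ld + bias[:, 17:18]
        f0 = denormalize_frequency(sigmoid(h_f0).reshape(T), r["f0"])
        ff_u = sigmoid(h_ff)
        ff = stack([denormalize_frequency(ff_u[:, i], r[f"f{i + 1}"])
                    for i in range(N_FORMANTS)], axis=1)
        lo, hi = r["b_bb"]
        return SpeechParams(
            f0=f0, formant_freq=ff, formant_amp=softplus(h_fa),
            bb_freq=denormalize_frequency(sigmoid(h_bb[:, 0]), r["f_bb"]),
            bb_bw=sigmoid(h_bb[:, 1]) * (hi - lo) + (lo + 1e-6),
            bb_amp=softplus(h_bb[:, 2]),
            alpha=sigmoid(h_al).reshape(T),
            loudness=softplus(h_ld).reshape(T),
        )


def _with_mask_channel(x: ECoGTensor) -> Tensor:
    """(T, H, W, 2): zero-filled signal plus broadcast validity mask."""
    vals = x.values * x.valid_mask[None, :, :]
    mask = np.broadcast_to(x.valid_mask[None, :, :].astype(np.float64),
                           vals.shape)
    return Tensor(np.stack([vals, mask], axis=-1))


def _lagged_bypass(skip: "Linear", flat: Tensor, T: int, n_lags: int) -> Tensor:
    """(T, 18) pre-activation bias from a causal window of lagged inputs."""
    lagged = concat([flat.pad(((lag, 0), (0, 0)))[:T]
                     for lag in range(n_lags)], axis=1)
    return skip(lagged)


def _pad_time(x: Tensor, multiple: int, causal: bool):
    """Pad the leading (time) axis to a multiple; left-pad if causal."""
    T = x.shape[0]
    extra = (-T) % multiple
    if extra == 0:
        return x, 0
    pw = [(extra, 0) if causal else (extra // 2, extra - extra // 2)]
    pw += [(0, 0)] * (x.ndim - 1)
    return x.pad(tuple(pw), mode="edge"), pw[0][0]


class ResNet3dDecoder(Module):
    """Temporal-conv stem, four 3D-conv residual blocks downsampling the
    electrode grid to 1x1 and time to T/16, transposed temporal convs back
    to T, then the shared prediction head."""

    def __init__(self, grid_shape, config: DecoderConfig = None, seed: int = 0):
        cfg = config or DecoderConfig()
        self.config = cfg
        self.causal = cfg.causal
        rng = np.random.default_rng(seed)
        C = cfg.channels
        H, W = grid_shape
        self.stem = Conv3d(2, C // 2, (5, 1, 1), rng, causal=cfg.causal)
        self.blocks = []
        self.skips = []
        h, w = H, W
        c_in = C // 2
        for _ in range(cfg.n_res_blocks):
            sh = 2 if h > 1 else 1
            sw = 2 if w > 1 else 1
            self.blocks.append([
                Conv3d(c_in, C, (3, 3, 3), rng, stride=(2, sh, sw),
                       causal=cfg.causal),
                Conv3d(C, C, (3, 3, 3), rng, causal=cfg.causal),
            ])
            self.skips.append(Conv3d(c_in, C, (1, 1, 1), rng,
                                     stride=(2, sh, sw), causal=cfg.causal))
            h, w = -(-h // sh), -(-w // sw)
            c_in = C
        self.ups = [UpsampleConv1d(C, C, 2, 3, rng, causal=cfg.causal)
                    for _ in range(cfg.n_res_blocks)]
        self.skip_lags = 4
        self.skip = Linear(2 * H * W * self.skip_lags, 18, rng)
        self.skip.weight.data *= 0.1
        self.head = ParamHead(C, cfg.head_hidden, cfg.ranges, rng,
                              causal=cfg.causal)

    def __call__(self, x: ECoGTensor) -> SpeechParams:
        T = x.n_frames
        feat = _with_mask_channel(x)
        flat = feat.reshape(T, -1)
        feat, offset = _pad_time(feat, 2 ** self.config.n_res_blocks,
                                 self.causal)
        feat = self.stem(feat).tanh()
        for (c1, c2), sk in zip(self.blocks, self.skips):
            feat = (c2(c1(feat).tanh()) + sk(feat)).tanh()
        t, h, w, C = feat.shape
        feat = feat.mean(axis=(1, 2)) if (h > 1 or w > 1) else feat.reshape(t, C)
        for up in self.ups:
            feat = up(feat).tanh()
        feat = feat[offset:offset + T]
        return self.head(feat, bias=_lagged_bypass(self.skip, flat, T,
                                                   self.skip_lags))


# ---------------------------------------------------------------------------
# 3D shifted-window transformer
# ---------------------------------------------------------------------------

class WindowAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng):
        self.n_heads = n_heads
        self.dim = dim
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, tokens: Tensor, bias: np.ndarray) -> Tensor:
        """tokens: (n_windows, n, dim); bias: additive mask (n_windows, n, n)."""
        nw, n, d = tokens.shape
        h = self.n_heads
        dh = d // h
        qkv = self.qkv(tokens).reshape(nw, n, 3, h, dh)
        q = qkv[:, :, 0].transpose(0, 2, 1, 3)    # (nw, h, n, dh)
        k = qkv[:, :, 1].transpose(0, 2, 1, 3)
        v = qkv[:, :, 2].transpose(0, 2, 1, 3)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        att = att + bias[:, None, :, :]
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(nw, n, d)
        return self.proj(out)


class SwinBlock(Module):
    def __init__(self, dim: int, n_heads: int, rng, ffn_ratio: int = 2):
        self.ln1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ffn = MLP(dim, ffn_ratio * dim, dim, rng)


def _window_bias(shape, window, shift, max_frame, causal) -> np.ndarray:
    """Additive attention bias for one (optionally shifted) window layer.

    Blocks attention across tokens that were not neighbours before the
    cyclic shift (the standard shifted-window mask) and — in causal mode —
    from any token to one whose latest source frame lies in its future.
    Returns (n_windows, n, n) with 0 for allowed pairs, -1e9 otherwise.
    """
    Tt, Hh, Ww = shape
    wt, wh, ww = window
    st, sh, sw = shift
    region = np.zeros(shape)
    cnt = 0
    for sl_t in _mask_slices(Tt, wt, st):
        for sl_h in _mask_slices(Hh, wh, sh):
            for sl_w in _mask_slices(Ww, ww, sw):
                region[sl_t, sl_h, sl_w] = cnt
                cnt += 1
    # region labels live in the shifted frame; the frame index tracks the
    # rolled content, so only it gets rolled
    mf = np.broadcast_to(np.asarray(max_frame)[:, None, None], shape)
    if st:
        mf = np.roll(mf, -st, axis=0)
    reg_w = _partition_np(region[..., None], window)[..., 0]   # (nw, n)
    mf_w = _partition_np(mf[..., None], window)[..., 0]
    allowed = reg_w[:, None, :] == reg_w[:, :, None]
    if causal:
        allowed &= mf_w[:, None, :] <= mf_w[:, :, None]
    return np.where(allowed, 0.0, -1e9)


def _mask_slices(size, win, shift):
    if shift == 0:
        return [slice(0, size)]
    return [slice(0, size - win), slice(size - win, size - shift),
            slice(size - shift, size)]


def _partition_np(x: np.ndarray, window):
    Tt, Hh, Ww, C = x.shape
    wt, wh, ww = window
    x = x.reshape(Tt // wt, wt, Hh // wh, wh, Ww // ww, ww, C)
    x = x.transpose(0, 2, 4, 1, 3, 5, 6)
    return x.reshape(-1, wt * wh * ww, C)


def _partition(x: Tensor, window):
    Tt, Hh, Ww, C = x.shape
    wt, wh, ww = window
    x = x.reshape(Tt // wt, wt, Hh // wh, wh, Ww // ww, ww, C)
    x = x.transpose(0, 2, 4, 1, 3, 5, 6)
    return x.reshape((Tt // wt) * (Hh // wh) * (Ww // ww), wt * wh * ww, C)


def _unpartition(x: Tensor, window, shape):
    Tt, Hh, Ww = shape
    wt, wh, ww = window
    x = x.reshape(Tt // wt, Hh // wh, Ww // ww, wt, wh, ww, x.shape[-1])
    x = x.transpose(0, 3, 1, 4, 2, 5, 6)
    return x.reshape(Tt, Hh, Ww, x.shape[-1])


class Swin3dDecoder(Module):
    """Hierarchical shifted-window attention over 2x2x2 ECoG tokens.

    Stages of (2, 2, 6) transformer layers with patch merging between
    stages; each layer alternates plain and shifted 3D windows. Causal
    variants restrict temporal attention to present-or-past tokens and use
    left-aligned temporal patching so no token aggregates future frames.
    """

    def __init__(self, grid_shape, config: DecoderConfig = None, seed: int = 0):
        cfg = config or DecoderConfig(backbone="swin3d")
        self.config = cfg
        self.causal = cfg.causal
        rng = np.random.default_rng(seed)
        C = cfg.channels
        self.patch_proj = Conv3d(2, cfg.patch_dim, cfg.patch, rng,
                                 stride=cfg.patch, causal=cfg.causal)
        self.embed = Linear(cfg.patch_dim, C, rng)
        self.stages = []
        self.mergers = []
        dim = C
        for si, n_layers in enumerate(cfg.swin_layers):
            self.stages.append([SwinBlock(dim, cfg.n_heads, rng)
                                for _ in range(n_layers)])
            if si < len(cfg.swin_layers) - 1:
                self.mergers.append(Linear(8 * dim, 2 * dim, rng))
                dim *= 2
        n_up = 1 + len(cfg.swin_layers) - 1   # patch embed + mergers
        self.ups = [UpsampleConv1d(dim, dim, 2, 3, rng, causal=cfg.causal)
                    for _ in range(n_up)]
        H, W = grid_shape
        self.skip_lags = 4
        self.skip = Linear(2 * H * W * self.skip_lags, 18, rng)
        self.skip.weight.data *= 0.1
        self.head = ParamHead(dim, cfg.head_hidden, cfg.ranges, rng,
                              causal=cfg.causal)

    # -- internals ---------------------------------------------------------

    def _attention_layer(self, x, block, shift_layer, max_frame):
        cfg = self.config
        Tt, Hh, Ww, C = x.shape
        win = (min(cfg.window[0], Tt), min(cfg.window[1], Hh),
               min(cfg.window[2], Ww))
        pad = [(-Tt) % win[0], (-Hh) % win[1], (-Ww) % win[2]]
        mf = np.concatenate([max_frame, np.full(pad[0], max_frame[-1])])
        if any(pad):
            x = x.pad(((0, pad[0]), (0, pad[1]), (0, pad[2]), (0, 0)),
                      mode="constant")
        shape = (Tt + pad[0], Hh + pad[1], Ww + pad[2])
        shift = tuple((w // 2 if (shift_layer and s > w) else 0)
                      for w, s in zip(win, shape))
        bias = _window_bias(shape, win, shift, mf, self.causal)
        h = x
        if any(shift):
            h = h.roll(tuple(-s for s in shift), axis=(0, 1, 2))
        tokens = _partition(block.ln1(h), win)
        att = block.attn(tokens, bias)
        att = _unpartition(att, win, shape)
        if any(shift):
            att = att.roll(shift, axis=(0, 1, 2))
        x = x + att
        x = x + block.ffn(block.ln2(x).reshape(-1, C)).reshape(x.shape)
        if any(pad):
            x = x[:Tt, :Hh, :Ww]
        return x

    def _merge(self, x, merger, max_frame):
        Tt, Hh, Ww, C = x.shape
        pt, ph, pw = (-Tt) % 2, (-Hh) % 2, (-Ww) % 2
        if pt or ph or pw:
            # left-pad time in causal mode so merged tokens never pull
            # content from a later frame slot
            tpad = (pt, 0) if self.causal else (0, pt)
            x = x.pad((tpad, (0, ph), (0, pw), (0, 0)), mode="edge")
            max_frame = (np.concatenate([max_frame[:1], max_frame])
                         if (self.causal and pt) else
                         np.concatenate([max_frame, max_frame[-1:]])
                         if pt else max_frame)
        Tt, Hh, Ww = x.shape[0], x.shape[1], x.shape[2]
        x = x.reshape(Tt // 2, 2, Hh // 2, 2, Ww // 2, 2, C)
        x = x.transpose(0, 2, 4, 1, 3, 5, 6).reshape(Tt // 2, Hh // 2, Ww // 2,
                                                     8 * C)
        mf = max_frame.reshape(-1, 2).max(axis=1)
        return merger(x.reshape(-1, 8 * C)).reshape(Tt // 2, Hh // 2, Ww // 2,
                                                    2 * C), mf

    def tokenize(self, x: ECoGTensor):
        """Patch partition + linear embedding; returns tokens and the
        per-temporal-index latest source frame."""
        T = x.n_frames
        feat = _with_mask_channel(x)
        # pad to the full temporal downsampling factor up front so patch
        # merging never needs to re-pad (keeps the timeline aligned)
        factor = self.config.patch[0] * 2 ** len(self.mergers)
        feat, offset = _pad_time(feat, factor, self.causal)
        tok = self.patch_proj(feat)
        Tt = tok.shape[0]
        pt = self.config.patch[0]
        if self.causal:
            mf = np.arange(Tt) * pt - offset   # token covers frames <= this
        else:
            mf = np.arange(Tt) * pt + (pt - 1) - offset
        tok = self.embed(tok.reshape(-1, self.config.patch_dim))
        tok = tok.reshape(Tt, feat.shape[1] // self.config.patch[1],
                          feat.shape[2] // self.config.patch[2], -1)
        return tok, mf, offset, T

    def __call__(self, x: ECoGTensor) -> SpeechParams:
        tok, mf, offset, T = self.tokenize(x)
        for si, stage in enumerate(self.stages):
            for li, block in enumerate(stage):
                tok = self._attention_layer(tok, block, li % 2 == 1, mf)
            if si < len(self.mergers):
                tok, mf = self._merge(tok, self.mergers[si], mf)
        t, h, w, C = tok.shape
        feat = tok.mean(axis=(1, 2)) if (h > 1 or w > 1) else tok.reshape(t, C)
        for up in self.ups:
            feat = up(feat).tanh()
        if self.causal:
            # merged tokens aggregate later frames than their left-aligned
            # upsampled position; delay the sequence so the output at frame
            # j only ever sees features built from frames <= j
            stride = self.config.patch[0] * 2 ** len(self.mergers)
            delay = int(max(0, np.max(mf + offset - stride * np.arange(t))))
            if delay:
                L = feat.shape[0]
                feat = feat.pad(((delay, 0), (0, 0)), mode="constant")[:L]
        feat = feat[offset:offset + T]
        flat = _with_mask_channel(x).reshape(T, -1)
        return self.head(feat, bias=_lagged_bypass(self.skip, flat, T,
                                                   self.skip_lags))


class LSTMDecoder(Module):
    """LSTM feature extraction (three layers, bidirectional when
    non-causal) + linear layer; the temporal dimension is unchanged across
    all layers.

    Two parallel trunks feed the shared prediction head: one for the
    frequency-valued parameters (whose gradients are dominated by the
    pitch/formant supervision) and one for the amplitude-like parameters
    (voice weight, loudness, amplitudes). Separating them keeps the
    strongly supervised frequency terms from monopolizing the recurrent
    features the amplitude heads depend on.
    """

    def __init__(self, grid_shape, config: DecoderConfig = None, seed: int = 0):
        cfg = config or DecoderConfig(backbone="lstm")
        self.config = cfg
        self.causal = cfg.causal
        rng = np.random.default_rng(seed)
        H, W = grid_shape
        self.lstm = LSTM(2 * H * W, cfg.channels, cfg.lstm_layers, rng,
                         bidirectional=not cfg.causal)
        self.linear = Linear(self.lstm.d_out, cfg.channels, rng)
        self.lstm_amp = LSTM(2 * H * W, cfg.channels, cfg.lstm_layers, rng,
                             bidirectional=not cfg.causal)
        self.linear_amp = Linear(self.lstm_amp.d_out, cfg.channels, rng)
        # linear bypass from a short causal window of lagged inputs into
        # every pre-activation: the generative map is near-linear in the
        # lagged electrode signals, and a direct linear path converges fast
        self.skip_lags = 4
        self.skip = Linear(2 * H * W * self.skip_lags, 18, rng)
        self.skip.weight.data *= 0.1
        self.head = ParamHead(cfg.channels, cfg.head_hidden, cfg.ranges, rng,
                              causal=cfg.causal, two_stream=True)

    def __call__(self, x: ECoGTensor) -> SpeechParams:
        T = x.n_frames
        flat = _with_mask_channel(x).reshape(T, -1)
        feat = self.linear(self.lstm(flat)).tanh()
        feat_amp = self.linear_amp(self.lstm_amp(flat)).tanh()
        return self.head(feat, feat_amp,
                         bias=_lagged_bypass(self.skip, flat, T,
                                             self.skip_lags))


_BACKBONES = {"resnet3d": ResNet3dDecoder, "swin3d": Swin3dDecoder,
              "lstm": LSTMDecoder}


def make_decoder(grid_shape, config: DecoderConfig = None, seed: int = 0):
    cfg = config or DecoderConfig()
    if cfg.backbone not in _BACKBONES:
        raise ValueError(f"unknown backbone {cfg.backbone!r}")
    return _BACKBONES[cfg.backbone](grid_shape, cfg, seed=seed)


def resnet_decode(x: ECoGTensor, state: ResNet3dDecoder,
                  causal: bool = None) -> SpeechParams:
    if causal is not None and causal != state.causal:
        raise ValueError("decoder state was built with the other causality")
    return state(x)


def swin_decode(x: ECoGTensor, state: Swin3dDecoder,
                causal: bool = None) -> SpeechParams:
    if causal is not None and causal != state.causal:
        raise ValueError("decoder state was built with the other causality")
    return state(x)


def lstm_decode(x: ECoGTensor, state: LSTMDecoder,
                causal: bool = None) -> SpeechParams:
    if causal is not None and causal != state.causal:
        raise ValueError("decoder state was built with the other causality")
    return state(x)


def causality_probe(decode_fn, x: ECoGTensor, t: int, rng=None,
                    atol: float = 1e-9) -> bool:
    """True iff outputs at frames <= t are invariant to randomizing frames > t.

    Vacuously true at ``t = T-1`` (no future frames exist to perturb).
    """
    if t >= x.n_frames:
        raise ValueError("probe time must lie within the input")
    rng = rng or np.random.default_rng(0)
    base = decode_fn(x).as_array()
    vals = x.values.copy()
    if t + 1 < x.n_frames:
        vals[t + 1:] = rng.normal(size=vals[t + 1:].shape)
    pert = ECoGTensor(vals, frame_rate=x.frame_rate, valid_mask=x.valid_mask)
    out = decode_fn(pert).as_array()
    return bool(np.max(np.abs(out[:t + 1] - base[:t + 1])) <= atol)


@dataclass
class DecoderTrainConfig:
    steps: int = 1000
    batch_size: int = 8
    lr: float = 1e-3
    lr_final: float = None      # cosine-decay target; None = constant lr
    weights: LossWeights = field(default_factory=LossWeights)


def train_decoder(dataset, speaker, decoder_config: DecoderConfig = None,
                  train_config: DecoderTrainConfig = None, seed: int = 0):
    """Train an ECoG decoder against encoder-guidance targets.

    ``dataset`` is a sequence of dicts with keys ``ecog`` (ECoGTensor),
    ``spectrogram`` (ground truth), ``guidance`` (reference SpeechParams
    from a trained speech encoder, or synthetic ground truth), ``f0`` and
    ``formants`` (supervision series). The speaker parameters stay fixed.
    Returns ``(decoder, history)``; deterministic given ``seed``.
    """
    if len(dataset) < 1:
        raise ValueError("need at least one training pair")
    cfg = train_config or DecoderTrainConfig()
    dcfg = decoder_config or DecoderConfig()
    rng = np.random.default_rng(seed)
    grid = dataset[0]["ecog"].grid_shape
    dec = make_decoder(grid, dcfg, seed=int(rng.integers(2 ** 31)))
    opt = Adam(dec.parameters(), lr=cfg.lr)
    history = []
    from .synth import synthesize
    for step in range(cfg.steps):
        if cfg.lr_final is not None:
            frac = 0.5 * (1 + np.cos(np.pi * step / max(cfg.steps - 1, 1)))
            opt.lr = cfg.lr_final + (cfg.lr - cfg.lr_final) * frac
        idx = rng.choice(len(dataset), size=min(cfg.batch_size, len(dataset)),
                         replace=False)
        opt.zero_grad()
        total = None
        for i in idx:
            tr = dataset[i]
            pred = dec(tr["ecog"])
            S_hat = synthesize(pred, speaker, seed=None)   # expected noise
            loss = decoder_total(S_hat.values, tr["spectrogram"].values, pred,
                                 tr["f0"], np.asarray(tr["formants"])[:, :4],
                                 tr["guidance"], cfg.weights, tr.get("voiced"))
            total = loss if total is None else total + loss
        total = total * (1.0 / len(idx))
        val = total.item()
        if not np.isfinite(val):
            raise RuntimeError(f"decoder training diverged at step {step}")
        total.backward()
        opt.step()
        history.append(val)
    return dec, history
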