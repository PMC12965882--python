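"""Neural-network building blocks on the :mod:`neurovox.autodiff` engine.

Layers hold their weights as ``Tensor`` leaves with ``requires_grad=True``
and are initialized from an explicit ``numpy.random.Generator`` so that every
training run is reproducible from a seed. Temporal layers support a
``causal`` flag: causal convolutions pad on the left only, so the output at
frame ``t`` never depends on inputs after ``t``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, sigmoid

__all__ = ["Module", "Linear", "Conv1d", "UpsampleConv1d", "Conv3d",
           "LayerNorm", "LSTM", "MLP", "Adam"]


class Module:
    """Base class: recursive parameter collection and state (de)serialization."""

    def parameters(self):
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        params.extend(v.parameters())
                    elif isinstance(v, Tensor) and v.requires_grad:
                        params.append(v)
        return params

    def state_dict(self, prefix=""):
        state = {}
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                state[key] = value.data.copy()
            elif isinstance(value, Module):
                state.update(value.state_dict(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        state.update(v.state_dict(prefix=f"{key}.{i}."))
                    elif isinstance(v, Tensor) and v.requires_grad:
                        state[f"{key}.{i}"] = v.data.copy()
        return state

    def load_state_dict(self, state, prefix=""):
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                value.data = np.asarray(state[key], dtype=np.float64).reshape(value.shape)
            elif isinstance(value, Module):
                value.load_state_dict(state, prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        v.load_state_dict(state, prefix=f"{key}.{i}.")
                    elif isinstance(v, Tensor) and v.requires_grad:
                        v.data = np.asarray(state[f"{key}.{i}"], dtype=np.float64).reshape(v.shape)


def _param(rng: np.random.Generator, shape, scale=None) -> Tensor:
    if scale is None:
        fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
        scale = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = _param(rng, (d_in, d_out))
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Two-layer perceptron with tanh hidden activation."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).tanh())


def _window_index(t_out: int, kernel: int, stride: int) -> np.ndarray:
    starts = np.arange(t_out) * stride
    return starts[:, None] + np.arange(kernel)[None, :]


class Conv1d(Module):
    """Temporal convolution on (T, C_in) sequences.

    ``causal=True`` pads ``kernel-1`` frames on the left (replicated edge),
    ``causal=False`` pads symmetrically; with ``stride=s`` the output frame
    ``i`` depends on input frames ``<= i*s`` in the causal case.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng,
                 stride: int = 1, causal: bool = False):
        self.kernel = kernel
        self.stride = stride
        self.causal = causal
        self.weight = _param(rng, (kernel * c_in, c_out))
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k, s = self.kernel, self.stride
        if self.causal:
            pad = (k - 1, 0)
        else:
            total = k - 1
            pad = (total // 2, total - total // 2)
        xp = x.pad(((pad[0], pad[1]), (0, 0)), mode="edge")
        t_out = (xp.shape[0] - k) // s + 1
        idx = _window_index(t_out, k, s)
        win = xp[idx]                       # (t_out, k, c_in)
        win = win.reshape(t_out, k * x.shape[1])
        return win @ self.weight + self.bias


class UpsampleConv1d(Module):
    """Temporal upsampling by integer factor: repeat then convolve.

    Causal alignment: the feature at coarse step ``i`` is copied onto output
    frames ``[i*factor, (i+1)*factor)``, so no future leakage is introduced.
    """

    def __init__(self, c_in: int, c_out: int, factor: int, kernel: int, rng,
                 causal: bool = False):
        self.factor = factor
        self.conv = Conv1d(c_in, c_out, kernel, rng, causal=causal)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x.repeat(self.factor, axis=0))


class Conv3d(Module):
    """3D convolution on (T, H, W, C_in) tensors with per-axis stride.

    The temporal axis honours ``causal``; spatial axes always pad
    symmetrically (space carries no causality constraint).
    """

    def __init__(self, c_in: int, c_out: int, kernel, rng,
                 stride=(1, 1, 1), causal: bool = False):
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.causal = causal
        k = int(np.prod(self.kernel))
        self.weight = _param(rng, (k * c_in, c_out))
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        (kt, kh, kw), (st, sh, sw) = self.kernel, self.stride
        if self.causal:
            pt = (kt - 1, 0)
        else:
            pt = ((kt - 1) // 2, kt - 1 - (kt - 1) // 2)
        ph = ((kh - 1) // 2, kh - 1 - (kh - 1) // 2)
        pw = ((kw - 1) // 2, kw - 1 - (kw - 1) // 2)
        xp = x.pad((pt, ph, pw, (0, 0)), mode="constant")
        to = (xp.shape[0] - kt) // st + 1
        ho = (xp.shape[1] - kh) // sh + 1
        wo = (xp.shape[2] - kw) // sw + 1
        it = _window_index(to, kt, st)
        ih = _window_index(ho, kh, sh)
        iw = _window_index(wo, kw, sw)
        win = xp[it[:, None, None, :, None, None],
                 ih[None, :, None, None, :, None],
                 iw[None, None, :, None, None, :]]   # (to,ho,wo,kt,kh,kw,C)
        win = win.reshape(to * ho * wo, kt * kh * kw * x.shape[3])
        out = win @ self.weight + self.bias
        return out.reshape(to, ho, wo, self.weight.shape[1])


class LayerNorm(Module):
    """Normalization over the last axis (per frame / per token)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


def _lstm_recurrence(xw: Tensor, wh: Tensor, d_hidden: int,
                     reverse: bool) -> Tensor:
    """Fused LSTM recurrence over precomputed input projections.

    ``xw`` is (T, 4H) = x @ Wx + b; the whole unrolled loop is one graph
    node with a hand-written backward pass (BPTT), which keeps the graph
    small and the python overhead per training step low.
    """
    T = xw.shape[0]
    H = d_hidden
    xwd, whd = xw.data, wh.data
    order = range(T - 1, -1, -1) if reverse else range(T)
    hs = np.zeros((T, H))
    cs = np.zeros((T, H))
    gates = np.zeros((T, 4 * H))
    h = np.zeros(H)
    c = np.zeros(H)
    for t in order:
        z = xwd[t] + h @ whd
        i = 1.0 / (1.0 + np.exp(-z[:H]))
        f = 1.0 / (1.0 + np.exp(-z[H:2 * H]))
        g = np.tanh(z[2 * H:3 * H])
        o = 1.0 / (1.0 + np.exp(-z[3 * H:]))
        c_new = f * c + i * g
        h = o * np.tanh(c_new)
        gates[t] = np.concatenate([i, f, g, o])
        cs[t] = c_new
        hs[t] = h
        c = c_new
    if not (xw.requires_grad or wh.requires_grad):
        return Tensor(hs)

    def backward(dH):
        steps = list(order)
        dxw = np.zeros_like(xwd)
        dwh = np.zeros_like(whd)
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for k in range(len(steps) - 1, -1, -1):
            t = steps[k]
            t_prev = steps[k - 1] if k > 0 else None
            c_prev = cs[t_prev] if t_prev is not None else np.zeros(H)
            h_prev = hs[t_prev] if t_prev is not None else np.zeros(H)
            i, f, g, o = np.split(gates[t], 4)
            tanh_c = np.tanh(cs[t])
            dh = dH[t] + dh_next
            dc = dc_next + dh * o * (1 - tanh_c ** 2)
            dz = np.concatenate([
                dc * g * i * (1 - i),
                dc * c_prev * f * (1 - f),
                dc * i * (1 - g * g),
                dh * tanh_c * o * (1 - o),
            ])
            dxw[t] = dz
            dwh += np.outer(h_prev, dz)
            dh_next = whd @ dz
            dc_next = dc * f
        if xw.requires_grad:
            xw._accum(dxw)
        if wh.requires_grad:
            wh._accum(dwh)

    return Tensor._make(hs, (xw, wh), backward)


class LSTMCellLayer(Module):
    """One unidirectional LSTM layer over a (T, D) sequence."""

    def __init__(self, d_in: int, d_hidden: int, rng):
        self.d_hidden = d_hidden
        self.wx = _param(rng, (d_in, 4 * d_hidden))
        self.wh = _param(rng, (d_hidden, 4 * d_hidden))
        b = np.zeros(4 * d_hidden)
        b[d_hidden:2 * d_hidden] = 1.0   # forget-gate bias
        self.bias = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor, reverse: bool = False):
        xw = x @ self.wx + self.bias        # (T, 4H)
        return _lstm_recurrence(xw, self.wh, self.d_hidden, reverse)


class LSTM(Module):
    """Stacked (optionally bidirectional) LSTM, temporal length preserved."""

    def __init__(self, d_in: int, d_hidden: int, n_layers: int, rng,
                 bidirectional: bool = False):
        self.bidirectional = bidirectional
        self.fwd = []
        self.bwd = []
        d = d_in
        for _ in range(n_layers):
            self.fwd.append(LSTMCellLayer(d, d_hidden, rng))
            if bidirectional:
                self.bwd.append(LSTMCellLayer(d, d_hidden, rng))
                d = 2 * d_hidden
            else:
                d = d_hidden
        self.d_out = d

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.fwd):
            if self.bidirectional:
                x = concat([layer(x), self.bwd[i](x, reverse=True)], axis=1)
            else:
                x = layer(x)
        return x


class Adam:
    """Adam optimizer (lr=1e-3, beta1=0.9, beta2=0.999 by default)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
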