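"""Differentiable source–filter speech synthesizer.

Maps 18 per-frame speech parameters plus time-invariant speaker parameters to
a magnitude spectrogram. Two pathways are softly mixed by the voice weight
``alpha``:

* voice pathway: a harmonic excitation at pitch ``f0`` (80 harmonics,
  partials above ``f_max`` removed) filtered by six formant filters;
* noise pathway: white-noise excitation filtered by a broadband unvoice
  filter plus the same six formant filters.

Each formant filter is a shifted and scaled copy of a learnable unimodal
prototype ``G_i`` (piecewise linear over M=80 uniform frequency samples,
peak 1): ``F_i(f) = a_i * G_i((b_proto/b_i) * (f - f_i) + f_proto)``, with
the bandwidth tied to the centre frequency through a learnable piecewise
linear relation ``b_i = a*(f_i - f_theta) + b0`` above the threshold
``f_theta`` and ``b0`` below it. The final spectrogram is
``S_hat = L * (alpha*V + (1-alpha)*U) + B(f)`` with learnable stationary
background ``B``. Everything is differentiable with respect to both the
per-frame parameters and the speaker parameters, so the synthesizer can sit
at the end of a speech encoder or an ECoG decoder during training.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, concat, sigmoid, softplus, where_mask
from .nn import Module
from .types import (BB_BW_MIN, F_MAX, FRAME_RATE, N_FORMANTS, SpeechParams,
                    Spectrogram)

M_PROTO = 80          # samples per prototype filter
N_HARMONICS = 80      # harmonics in the voice excitation
PROFILES = {"female": 256, "male": 512}   # frequency bins K per voice profile

__all__ = ["SpeakerParams", "bandwidth_from_center", "prototype_filter_eval",
           "prototype_peak_bandwidth", "formant_filter_response",
           "harmonic_excitation", "noise_excitation", "voice_component",
           "unvoice_component", "synthesize", "count_learnable_params",
           "spectrogram_to_waveform", "waveform_to_spectrogram",
           "M_PROTO", "N_HARMONICS", "PROFILES"]


class InvalidParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# speaker parameters
# ---------------------------------------------------------------------------

def _inv_softplus(y):
    y = np.asarray(y, dtype=np.float64)
    return np.where(y > 30, y, np.log(np.expm1(np.clip(y, 1e-12, None))))


def _logit(p):
    p = np.clip(np.asarray(p, dtype=np.float64), 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def check_unimodal(g: np.ndarray, atol: float = 1e-8):
    """Raise unless ``g`` rises to a single peak of value 1 then falls."""
    g = np.asarray(g, dtype=np.float64)
    p = int(np.argmax(g))
    d = np.diff(g)
    if np.any(d[:p] < -atol) or np.any(d[p:] > atol):
        raise InvalidParameterError("prototype samples are not unimodal")
    if abs(g[p] - 1.0) > 1e-6:
        raise InvalidParameterError("prototype peak must equal 1")


class SpeakerParams(Module):
    """Time-invariant learnable synthesizer parameters for one speaker.

    Unconstrained raw arrays are stored; constrained views are built on the
    fly so gradient descent cannot violate the invariants:

    * prototypes: each filter's M samples rise monotonically to a single
      peak of exactly 1 then fall, built from per-step sigmoid ratios;
    * bandwidth relation: per-formant triples (f_theta, slope, b0) with
      f_theta in [0, f_max], slope >= 0, b0 > 0;
    * background spectrum: K nonnegative bins via softplus.
    """

    def __init__(self, proto_raw, bw_raw, bg_raw, peak_idx, f_max: float = F_MAX):
        self.proto_raw = Tensor(proto_raw, requires_grad=True)   # (7, M)
        self.bw_raw = Tensor(bw_raw, requires_grad=True)         # (6, 3)
        self.bg_raw = Tensor(bg_raw, requires_grad=True)         # (K,)
        self.peak_idx = np.asarray(peak_idx, dtype=int)          # (7,) fixed
        self.f_max = float(f_max)
        if self.proto_raw.shape != (N_FORMANTS + 1, M_PROTO):
            raise InvalidParameterError("proto_raw must be (7, 80)")
        if self.bw_raw.shape != (N_FORMANTS, 3):
            raise InvalidParameterError("bw_raw must be (6, 3)")
        if self.bg_raw.data.ndim != 1 or self.bg_raw.shape[0] not in PROFILES.values():
            raise InvalidParameterError("background must have K in {256, 512} bins")

    # -- constrained views -------------------------------------------------

    def prototypes(self) -> Tensor:
        """(7, M) unimodal prototype samples, peak value exactly 1."""
        n, M = self.proto_raw.shape
        r = sigmoid(self.proto_raw)
        s = r.log()                                   # negative log-ratios
        cs = concat([Tensor(np.zeros((n, 1))), s.cumsum(axis=1)], axis=1)
        rows = np.arange(n)
        p = self.peak_idx
        cs_p = cs[rows, p].reshape(n, 1)
        cs_p1 = cs[rows, p + 1].reshape(n, 1)
        left = np.arange(M)[None, :] <= p[:, None]
        # m <= p: exp(sum_{j=m}^{p-1} log r_j); m > p: exp(sum_{j=p+1}^{m})
        expo = where_mask(left, cs_p - cs[:, :M], cs[:, 1:] - cs_p1)
        return expo.exp()

    def bw_triples(self):
        """Per-formant (f_theta, slope, b0): three (6,) tensors."""
        f_theta = sigmoid(self.bw_raw[:, 0]) * self.f_max
        slope = softplus(self.bw_raw[:, 1])
        b0 = softplus(self.bw_raw[:, 2]) + 1.0
        return f_theta, slope, b0

    def background(self) -> Tensor:
        """(K,) nonnegative stationary background spectrum."""
        return softplus(self.bg_raw)

    @property
    def n_bins(self) -> int:
        return self.bg_raw.shape[0]

    def count_learnable(self) -> int:
        """Total scalar learnable parameters (prototypes + relation + B)."""
        return sum(int(p.size) for p in self.parameters())

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_components(cls, prototypes, bw_triples, background,
                        f_max: float = F_MAX) -> "SpeakerParams":
        """Build raw parameters reproducing the given constrained values."""
        prototypes = np.asarray(prototypes, dtype=np.float64)
        bw_triples = np.asarray(bw_triples, dtype=np.float64)
        background = np.asarray(background, dtype=np.float64)
        n, M = prototypes.shape
        proto_raw = np.zeros((n, M))
        peak_idx = np.zeros(n, dtype=int)
        for i in range(n):
            g = prototypes[i]
            check_unimodal(g)
            p = int(np.argmax(g))
            peak_idx[i] = p
            r = np.full(M, 0.5)
            if p > 0:
                r[:p] = g[:p] / np.clip(g[1:p + 1], 1e-300, None)
            if p < M - 1:
                r[p + 1:] = g[p + 1:] / np.clip(g[p:M - 1], 1e-300, None)
            proto_raw[i] = _logit(r)
        if np.any(bw_triples[:, 2] <= 0):
            raise InvalidParameterError("baseline bandwidth b0 must be positive")
        bw_raw = np.stack([
            _logit(bw_triples[:, 0] / f_max),
            _inv_softplus(bw_triples[:, 1]),
            _inv_softplus(np.clip(bw_triples[:, 2] - 1.0, 1e-9, None)),
        ], axis=1)
        bg_raw = _inv_softplus(background)
        return cls(proto_raw, bw_raw, bg_raw, peak_idx, f_max=f_max)

    @classmethod
    def default(cls, profile: str = "female", seed: int = 0) -> "SpeakerParams":
        """Generic initialization for training from scratch."""
        if profile not in PROFILES:
            raise InvalidParameterError(f"unknown voice profile {profile!r}")
        K = PROFILES[profile]
        rng = np.random.default_rng(seed)
        grid = np.linspace(0.0, F_MAX, M_PROTO)
        protos = []
        centres = np.linspace(1500, 4500, N_FORMANTS + 1) + rng.uniform(-200, 200, N_FORMANTS + 1)
        widths = rng.uniform(600, 1200, N_FORMANTS + 1)
        for c, w in zip(centres, widths):
            g = np.exp(-0.5 * ((grid - c) / w) ** 2)
            g /= g.max()
            protos.append(g)
        bw = np.column_stack([
            np.full(N_FORMANTS, 500.0),
            np.full(N_FORMANTS, 0.06),
            np.full(N_FORMANTS, 80.0),
        ])
        background = np.full(K, 1e-3)
        return cls.from_components(np.array(protos), bw, background)


def count_learnable_params(voice_profile: str) -> int:
    """Scalar learnable synthesizer parameters for a voice profile.

    M(N+1) prototype samples + 18 bandwidth-relation parameters + K
    background bins (K = 256 female, 512 male).
    """
    if voice_profile not in PROFILES:
        raise InvalidParameterError(f"unknown voice profile {voice_profile!r}")
    K = PROFILES[voice_profile]
    return M_PROTO * (N_FORMANTS + 1) + 3 * N_FORMANTS + K


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def bandwidth_from_center(f_c, relation):
    """Bandwidth from centre frequency: a*(f_c - f_theta) + b0 above the
    threshold, b0 below; continuous at f_theta.

    ``relation`` is a (f_theta, slope, b0) triple of floats or tensors.
    """
    f_theta, slope, b0 = relation
    if not any(isinstance(v, Tensor) for v in (f_c, f_theta, slope, b0)):
        f_c = np.asarray(f_c, dtype=np.float64)
        if np.asarray(b0) <= 0:
            raise InvalidParameterError("baseline bandwidth b0 must be positive")
        bw = np.where(f_c > f_theta, slope * (f_c - f_theta) + b0, b0)
        if np.any(bw <= 0):
            raise InvalidParameterError("bandwidth relation yields non-positive bandwidth")
        return bw if bw.ndim else float(bw)
    # differentiable path: relu keeps the two branches and continuity
    return (as_tensor(f_c) - f_theta).relu() * slope + b0


def _clip_range(x: Tensor, lo: float, hi: float) -> Tensor:
    return -((-(x.clip_min(lo))).clip_min(-hi))


def pwl_interp(samples, x, f_max: float = F_MAX):
    """Piecewise-linear interpolation of M uniform samples over [0, f_max].

    Differentiable with respect to both the samples and the query points;
    queries outside [0, f_max] clamp to the endpoint samples.
    """
    samples = as_tensor(samples)
    x = as_tensor(x)
    M = samples.shape[-1]
    step = f_max / (M - 1)
    pos = _clip_range(x * (1.0 / step), 0.0, float(M - 1) - 1e-9)
    i0 = np.floor(pos.data).astype(int)
    i0 = np.clip(i0, 0, M - 2)
    w = pos - i0
    s0 = samples[i0]
    s1 = samples[i0 + 1]
    return s0 * (1.0 - w) + s1 * w


def prototype_filter_eval(proto_samples, f, f_max: float = F_MAX):
    """Evaluate a unimodal prototype filter at frequencies ``f`` (Hz)."""
    if not isinstance(proto_samples, Tensor):
        check_unimodal(proto_samples)
    return pwl_interp(proto_samples, f, f_max=f_max)


def prototype_peak_bandwidth(proto_samples, f_max: float = F_MAX):
    """Peak frequency and half-power bandwidth of a prototype filter.

    The half-power band is the frequency span where the piecewise-linear
    gain is >= peak/sqrt(2); crossings are solved exactly on the linear
    segments. Returns ``(f_proto, b_proto)`` in Hz.
    """
    g = proto_samples.data if isinstance(proto_samples, Tensor) else \
        np.asarray(proto_samples, dtype=np.float64)
    M = g.shape[0]
    grid = np.linspace(0.0, f_max, M)
    p = int(np.argmax(g))
    f_proto = grid[p]
    thr = g[p] / np.sqrt(2.0)

    def crossing(i):  # linear crossing of thr between knots i and i+1
        y0, y1 = g[i], g[i + 1]
        t = (thr - y0) / (y1 - y0)
        return grid[i] + t * (grid[i + 1] - grid[i])

    lo = grid[0]
    for i in range(p - 1, -1, -1):
        if g[i] < thr <= g[i + 1]:
            lo = crossing(i)
            break
    hi = grid[-1]
    for i in range(p, M - 1):
        if g[i] >= thr > g[i + 1]:
            hi = crossing(i)
            break
    return f_proto, hi - lo


def formant_filter_response(proto_samples, f_c, bw, amp, f_grid,
                            f_max: float = F_MAX):
    """Shifted/scaled prototype filter response on a frequency grid.

    ``F(f) = amp * G((b_proto/bw) * (f - f_c) + f_proto)``; maximum ``amp``
    at ``f = f_c``, half-power width ``bw``. ``f_c``, ``bw`` and ``amp`` may
    be scalars or per-frame (T,) series; the result is (K,) or (T, K).
    """
    tensor_path = any(isinstance(v, Tensor) for v in (proto_samples, f_c, bw, amp))
    if not tensor_path and np.any(np.asarray(bw) <= 0):
        raise InvalidParameterError("filter bandwidth must be positive")
    f_proto, b_proto = prototype_peak_bandwidth(proto_samples, f_max=f_max)
    f_c, bw, amp = as_tensor(f_c), as_tensor(bw), as_tensor(amp)
    f_grid = np.asarray(f_grid, dtype=np.float64)
    if f_c.ndim == 1:
        T = f_c.shape[0]
        f_c, bw = f_c.reshape(T, 1), bw.reshape(T, 1)
        amp = amp.reshape(T, 1)
        grid = f_grid[None, :]
    else:
        grid = f_grid
    arg = (Tensor(grid) - f_c) * (b_proto / bw) + f_proto
    gain = pwl_interp(proto_samples, arg, f_max=f_max)
    out = gain * amp
    return out if tensor_path else out.data


# ---------------------------------------------------------------------------
# excitations
# ---------------------------------------------------------------------------

def harmonic_excitation(f0, n_bins: int, f_max: float = F_MAX,
                        n_harmonics: int = N_HARMONICS,
                        sigma_bins: float = 1.2):
    """Magnitude spectrogram of the harmonic (voice) excitation.

    Each active harmonic k contributes a unit-peak spectral-resolution
    kernel centred at ``k*f0`` (the mainlobe a short-time transform of a
    sinusoid would place there); harmonics with ``k*f0 > f_max`` are removed
    so no aliased partials appear, and frames with ``f0 <= 0`` are silent.
    Differentiable with respect to ``f0`` with an analytic Jacobian.
    Returns a (T, n_bins) tensor.
    """
    f0_t = as_tensor(f0)
    f0d = f0_t.data
    if np.any(f0d < 0):
        raise InvalidParameterError("f0 must be nonnegative")
    T, K = f0d.shape[0], n_bins
    df = f_max / K
    sigma = sigma_bins * df
    half = int(np.ceil(5.0 * sigma / df))
    offs = np.arange(-half, half + 1)
    rows = np.arange(T)[:, None]
    H = np.zeros((T, K))
    D = np.zeros((T, K))     # dH/df0 per (frame, bin)
    for k in range(1, n_harmonics + 1):
        fk = k * f0d
        active = (f0d > 0) & (fk <= f_max)
        if not active.any():
            continue
        idx0 = np.rint(fk / df).astype(int)
        cols = idx0[:, None] + offs[None, :]
        valid = (cols >= 0) & (cols < K) & active[:, None]
        colsc = np.clip(cols, 0, K - 1)
        z = (colsc * df - fk[:, None]) / sigma
        bump = np.exp(-0.5 * z * z) * valid
        np.add.at(H, (np.broadcast_to(rows, cols.shape), colsc), bump)
        np.add.at(D, (np.broadcast_to(rows, cols.shape), colsc),
                  bump * z * (k / sigma))
    if not f0_t.requires_grad:
        return Tensor(H)

    def backward(g):
        f0_t._accum((g * D).sum(axis=1))

    return Tensor._make(H, (f0_t,), backward)


def noise_excitation(n_frames: int, n_bins: int, seed) -> np.ndarray:
    """Seeded white-noise magnitude spectrogram of unit expected power.

    Per-bin magnitudes of Gaussian white noise are Rayleigh distributed; we
    draw them directly with E[N^2] = 1. Passing ``seed=None`` returns the
    expected magnitude sqrt(pi)/2 in every bin (mean-field synthesis, used
    when a deterministic decoded spectrogram is wanted for evaluation).
    """
    if seed is None:
        return np.full((n_frames, n_bins), np.sqrt(np.pi) / 2.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.rayleigh(scale=np.sqrt(0.5), size=(n_frames, n_bins))


# ---------------------------------------------------------------------------
# pathway components and the full synthesizer
# ---------------------------------------------------------------------------

def _summed_formant_filter(p: SpeechParams, s: SpeakerParams, f_grid):
    protos = s.prototypes()
    f_theta, slope, b0 = s.bw_triples()
    total = None
    for i in range(N_FORMANTS):
        f_c = as_tensor(p.formant_freq)[:, i]
        amp = as_tensor(p.formant_amp)[:, i]
        bw = bandwidth_from_center(f_c, (f_theta[i], slope[i], b0[i]))
        resp = formant_filter_response(protos[i], f_c, bw, amp, f_grid,
                                       f_max=s.f_max)
        total = resp if total is None else total + resp
    return total


def _voice_from_filter(p: SpeechParams, s: SpeakerParams, F_v: Tensor) -> Tensor:
    H = harmonic_excitation(as_tensor(p.f0), s.n_bins, f_max=s.f_max)
    return F_v * H


def _unvoice_from_filter(p: SpeechParams, s: SpeakerParams, F_form: Tensor,
                         protos: Tensor, seed) -> Tensor:
    bb_bw = p.bb_bw.data if isinstance(p.bb_bw, Tensor) else np.asarray(p.bb_bw)
    if np.any(bb_bw <= BB_BW_MIN):
        raise InvalidParameterError("broadband bandwidth must exceed 2000 Hz")
    f_grid = np.arange(s.n_bins) * (s.f_max / s.n_bins)
    F_bb = formant_filter_response(protos[N_FORMANTS], as_tensor(p.bb_freq),
                                   as_tensor(p.bb_bw), as_tensor(p.bb_amp),
                                   f_grid, f_max=s.f_max)
    N = noise_excitation(p.n_frames, s.n_bins, seed)
    return (F_bb + F_form) * N


def voice_component(p: SpeechParams, s: SpeakerParams) -> Tensor:
    """Voiced pathway: summed formant filters times harmonic excitation."""
    f_grid = np.arange(s.n_bins) * (s.f_max / s.n_bins)
    return _voice_from_filter(p, s, _summed_formant_filter(p, s, f_grid))


def unvoice_component(p: SpeechParams, s: SpeakerParams, seed=0) -> Tensor:
    """Noise pathway: broadband + formant filters times white noise."""
    f_grid = np.arange(s.n_bins) * (s.f_max / s.n_bins)
    return _unvoice_from_filter(p, s, _summed_formant_filter(p, s, f_grid),
                                s.prototypes(), seed)


def synthesize(p: SpeechParams, s: SpeakerParams, seed=0,
               keep_graph: bool = None) -> Spectrogram:
    """Full synthesis: ``S_hat = L * (alpha*V + (1-alpha)*U) + B``.

    Returns a :class:`Spectrogram` whose ``values`` is an autodiff tensor
    when the speech parameters carry gradients (or ``keep_graph=True``,
    e.g. to differentiate with respect to the speaker parameters alone);
    otherwise a plain array. ``seed=None`` substitutes the expected noise
    magnitude for the sampled noise excitation (deterministic output).
    """
    T = p.n_frames
    for name in ("alpha", "loudness", "bb_freq"):
        arr = getattr(p, name)
        n = arr.shape[0] if isinstance(arr, Tensor) else np.asarray(arr).shape[0]
        if n != T:
            raise ValueError("speech-parameter series disagree on frame count")
    f_grid = np.arange(s.n_bins) * (s.f_max / s.n_bins)
    F_form = _summed_formant_filter(p, s, f_grid)   # shared by both pathways
    V = _voice_from_filter(p, s, F_form)
    U = _unvoice_from_filter(p, s, F_form, s.prototypes(), seed)
    alpha = as_tensor(p.alpha).reshape(T, 1)
    loud = as_tensor(p.loudness).reshape(T, 1)
    mix = alpha * V + (1.0 - alpha) * U
    out = loud * mix + s.background()
    if keep_graph is None:
        keep_graph = any(isinstance(getattr(p, f), Tensor)
                         and getattr(p, f).requires_grad
                         for f in ("f0", "formant_freq", "formant_amp",
                                   "bb_freq", "bb_bw", "bb_amp", "alpha",
                                   "loudness"))
    if keep_graph and out.requires_grad:
        return Spectrogram(out)
    return Spectrogram(out.data)


# ---------------------------------------------------------------------------
# waveform plumbing (analysis + Griffin–Lim inversion)
# ---------------------------------------------------------------------------

def _stft_params(n_bins: int, frame_rate: float = FRAME_RATE,
                 f_max: float = F_MAX):
    sr = int(2 * f_max)
    hop = int(round(sr / frame_rate))
    nperseg = 2 * n_bins
    return sr, hop, nperseg


def waveform_to_spectrogram(wav: np.ndarray, n_bins: int = 256,
                            frame_rate: float = FRAME_RATE,
                            f_max: float = F_MAX) -> Spectrogram:
    """Magnitude spectrogram (frames x K) of a 16 kHz mono waveform."""
    from scipy.signal import stft
    sr, hop, nperseg = _stft_params(n_bins, frame_rate, f_max)
    _, _, Z = stft(np.asarray(wav, dtype=np.float64), fs=sr, window="hann",
                   nperseg=nperseg, noverlap=nperseg - hop, boundary="zeros")
    mag = np.abs(Z).T[:, :n_bins]     # drop the Nyquist bin to keep K bins
    return Spectrogram(mag, frame_rate=frame_rate, f_max=f_max)


def spectrogram_to_waveform(spec: Spectrogram, n_iter: int = 32, seed: int = 0,
                            return_errors: bool = False):
    """Griffin–Lim phase reconstruction of a magnitude spectrogram.

    Iteratively projects between the magnitude constraint and the set of
    consistent STFTs; the reconstruction error is non-increasing.
    """
    from scipy.signal import istft, stft
    S = spec.data
    spec.validate()
    T, K = S.shape
    sr, hop, nperseg = _stft_params(K, spec.frame_rate, spec.f_max)
    mag = np.concatenate([S, np.zeros((T, 1))], axis=1).T   # (K+1, T)
    rng = np.random.default_rng(seed)
    phase = np.exp(2j * np.pi * rng.random(mag.shape))
    errors = []
    x = None
    for _ in range(max(n_iter, 1)):
        _, x = istft(mag * phase, fs=sr, window="hann", nperseg=nperseg,
                     noverlap=nperseg - hop, input_onesided=True)
        _, _, Z = stft(x, fs=sr, window="hann", nperseg=nperseg,
                       noverlap=nperseg - hop, boundary="zeros")
        Z = Z[:, :mag.shape[1]]
        errors.append(float(np.linalg.norm(np.abs(Z) - mag[:, :Z.shape[1]])))
        phase = np.exp(1j * np.angle(np.pad(Z, ((0, 0), (0, mag.shape[1] - Z.shape[1])))))
    if return_errors:
        return x, errors
    return x
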