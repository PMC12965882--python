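"""Training objectives: multi-scale spectral loss, STOI+ intelligibility,
parameter supervision and reference losses, and their weighted totals.

All losses are differentiable with respect to the predicted spectrogram and
speech parameters via the autodiff engine, and accept plain arrays for
evaluation-only use. Every term is normalized per element (means over
frames and cells): the published weights multiply values of comparable O(1)
magnitude, which is the only scale on which they can trade off against the
bounded STOI term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor
from .types import F_MAX, PARAM_NAMES, SpeechParams, Spectrogram

N_OCTAVE_BANDS = 15
OCTAVE_LOWEST_CENTER = 150.0   # Hz
STOI_SEGMENT = 30              # frames per short-time envelope segment

#: per-parameter reference-loss weights (voice weight, loudness, pitch,
#: formant frequencies/amplitudes, broadband triple)
REFERENCE_WEIGHTS = {
    "alpha": 1.8, "loudness": 1.5, "f0": 0.4,
    "f1": 3.0, "f2": 1.8, "f3": 1.2, "f4": 0.9, "f5": 0.6, "f6": 0.3,
    "a1": 4.0, "a2": 2.4, "a3": 1.2, "a4": 0.9, "a5": 0.6, "a6": 0.3,
    "f_bb": 10.0, "a_bb": 4.0, "b_bb": 4.0,
}

SUPERVISION_BETAS = (0.1, 0.06, 0.03, 0.02)


@dataclass
class LossWeights:
    """Weights of the loss stack (defaults are the tuned values)."""

    lambda1: float = 1.2        # STOI loss weight
    lambda2: float = 0.1        # supervision loss weight
    lambda3: float = 1.0        # reference loss weight (decoder training)
    beta: tuple = SUPERVISION_BETAS
    reference: dict = field(default_factory=lambda: dict(REFERENCE_WEIGHTS))


@dataclass
class BandDecomposition:
    """One-third-octave band analysis of a spectrogram."""

    band_edges: np.ndarray      # (15, 2) DFT-bin indices [k1, k2)
    band_norms: object          # (T, 15) energies (array or tensor)
    centers: np.ndarray         # (15,) centre frequencies, Hz


def _vals(x):
    if isinstance(x, Spectrogram):
        x = x.values
    return as_tensor(x)


def mel_filterbank(n_bins: int, n_mels: int = 80, f_max: float = F_MAX) -> np.ndarray:
    """Triangular Mel filterbank matrix (n_bins x n_mels) over [0, f_max]."""
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(0.0, hz_to_mel(f_max), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    freqs = np.arange(n_bins) * (f_max / n_bins)
    fb = np.zeros((n_bins, n_mels))
    for m in range(n_mels):
        lo, c, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (freqs - lo) / max(c - lo, 1e-9)
        down = (hi - freqs) / max(hi - c, 1e-9)
        fb[:, m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mss_loss(S_hat, S, n_mels: int = 80, log_floor_rel: float = 1e-6):
    """Modified multi-scale spectral loss.

    ``L(x, y) = |x - y| + |log x - log y|`` averaged per time-frequency
    cell, evaluated on the linear-scale spectrograms and on their Mel-scale
    projections, then summed over the two scales.
    Logs are floored at ``log_floor_rel`` times the reference dynamic range
    so the loss is finite and zero iff the spectrograms agree.
    """
    x, y = _vals(S_hat), _vals(S)
    if x.shape != y.shape:
        raise ValueError("spectrogram shapes disagree")
    eps = max(float(np.max(y.data)) * log_floor_rel, 1e-12)

    # means per time-frequency cell: keeps L_MSS O(1) so the STOI weight
    # (1.2 on a value in [-1, 1]) weighs the two terms comparably
    def term(a, b):
        lin = (a - b).abs().mean()
        lg = (a.clip_min(eps).log() - b.clip_min(eps).log()).abs().mean()
        return lin + lg

    fb = mel_filterbank(x.shape[1], n_mels=n_mels)
    total = term(x, y) + term(x @ fb, y @ fb)
    return total if total.requires_grad else total.item()


def octave_band_edges(n_bins: int, f_max: float = F_MAX):
    """DFT-bin edges of the 15 one-third-octave bands (lowest centre 150 Hz).

    Edges are rounded to the nearest bin (ties resolved downward). Raises if
    the spectral resolution cannot separate the lowest band or if ``f_max``
    does not cover the highest band (~4.3 kHz).
    """
    j = np.arange(N_OCTAVE_BANDS)
    centers = OCTAVE_LOWEST_CENTER * 2.0 ** (j / 3.0)
    lo = centers * 2.0 ** (-1.0 / 6.0)
    hi = centers * 2.0 ** (1.0 / 6.0)
    if f_max < hi[-1]:
        raise ValueError("f_max must cover the highest one-third-octave band (~4.3 kHz)")
    df = f_max / n_bins
    k1 = np.ceil(lo / df - 0.5).astype(int)          # round half down
    k2 = np.ceil(hi / df - 0.5).astype(int)
    if np.any(k2 <= k1):
        raise ValueError("spectrogram too coarse to resolve the lowest one-third-octave band")
    return np.stack([k1, k2], axis=1), centers


def octave_band_norms(spec) -> BandDecomposition:
    """Band norms ``X_j(m) = sqrt(sum_{k1<=k<k2} |x(k, m)|^2)``."""
    x = _vals(spec)
    edges, centers = octave_band_edges(x.shape[1],
                                       spec.f_max if isinstance(spec, Spectrogram) else F_MAX)
    Bmat = np.zeros((x.shape[1], N_OCTAVE_BANDS))
    for jj, (k1, k2) in enumerate(edges):
        Bmat[k1:k2, jj] = 1.0
    energy = (x * x) @ Bmat
    norms = (energy + 1e-20).sqrt()
    if not norms.requires_grad:
        norms = norms.data
    return BandDecomposition(band_edges=edges, band_norms=norms, centers=centers)


def stoi_plus(x, y, n_seg: int = STOI_SEGMENT):
    """STOI+ intelligibility between two spectrograms.

    One-third-octave band norms are segmented into overlapping ``n_seg``
    frame envelopes; the metric is the mean Pearson correlation between
    matched envelope segments over all bands and frames, in [-1, 1]. No
    clipping or normalization is applied. Zero-variance segments contribute
    0 to the average.
    """
    xs, ys = _vals(x), _vals(y)
    if xs.shape != ys.shape:
        raise ValueError("spectrogram shapes disagree")
    T = xs.shape[0]
    if T < n_seg:
        raise ValueError(f"need at least {n_seg} frames for STOI+")
    X = octave_band_norms(x).band_norms
    Y = octave_band_norms(y).band_norms
    X, Y = as_tensor(X), as_tensor(Y)
    idx = np.arange(T - n_seg + 1)[:, None] + np.arange(n_seg)[None, :]
    Xs = X[idx]                      # (n_segments, n_seg, 15)
    Ys = Y[idx]
    Xc = Xs - Xs.mean(axis=1, keepdims=True)
    Yc = Ys - Ys.mean(axis=1, keepdims=True)
    num = (Xc * Yc).sum(axis=1)
    vx = (Xc * Xc).sum(axis=1)
    vy = (Yc * Yc).sum(axis=1)
    ok = (vx.data > 1e-24) & (vy.data > 1e-24)
    den = (vx.clip_min(1e-24) * vy.clip_min(1e-24)).sqrt()
    d = num / den * ok
    out = d.mean()
    return out if out.requires_grad else out.item()


def supervision_loss(pred: SpeechParams, ref_f0, ref_formants,
                     beta=SUPERVISION_BETAS, voiced_mask=None):
    """Pitch and first-four-formant supervision (squared error in Hz).

    ``L = ||f0_hat - f0||^2 + sum_{i=1..4} beta_i ||fi_hat - fi||^2`` in
    Hz, squared norms averaged over (supervised) frames; formants 5 and 6
    are unsupervised. ``voiced_mask`` restricts the terms to frames where
    pitch/formant references are defined (pitch trackers emit no estimate
    in unvoiced spans).
    """
    f0 = as_tensor(pred.f0)
    ref_f0 = as_tensor(ref_f0)
    ref_formants = as_tensor(ref_formants)
    if f0.shape != ref_f0.shape or ref_formants.shape[0] != f0.shape[0]:
        raise ValueError("supervision series must align with prediction frames")
    if voiced_mask is None:
        m, n = 1.0, f0.shape[0]
    else:
        m = np.asarray(voiced_mask, dtype=np.float64)
        n = max(m.sum(), 1.0)
    d0 = f0 - ref_f0
    total = (d0 * d0 * m).sum() * (1.0 / n)
    ff = as_tensor(pred.formant_freq)
    for i, b in enumerate(beta):
        di = ff[:, i] - ref_formants[:, i]
        total = total + (b / n) * (di * di * m).sum()
    return total if total.requires_grad else total.item()


def _normalizers(ranges=None):
    """Scale factors taking each parameter to an O(1) range.

    Frequency-valued parameters are scaled by their allowed span so the
    printed reference weights are comparable across parameters.
    """
    from .encoder import DEFAULT_RANGES
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    scale = {}
    for name in PARAM_NAMES:
        if name in r:
            lo, hi = r[name]
            scale[name] = 1.0 / (hi - lo)
        else:
            scale[name] = 1.0
    return scale


def reference_loss(pred: SpeechParams, ref: SpeechParams, weights=None,
                   ranges=None):
    """Weighted squared error between decoded and reference parameters.

    ``L = sum_j lambda_j ||C_j_hat - C_j||^2`` over all 18 parameters
    (squared norms averaged over frames), with the tuned per-parameter
    weights; frequency-valued parameters are compared on their normalized
    [0, 1] scales.
    """
    w = dict(REFERENCE_WEIGHTS)
    if weights:
        w.update(weights)
    scale = _normalizers(ranges)

    def col(sp, name):
        if name == "f0":
            return as_tensor(sp.f0)
        if name.startswith("f") and name[1:].isdigit():
            return as_tensor(sp.formant_freq)[:, int(name[1:]) - 1]
        if name.startswith("a") and name[1:].isdigit():
            return as_tensor(sp.formant_amp)[:, int(name[1:]) - 1]
        return as_tensor(getattr(sp, {"f_bb": "bb_freq", "b_bb": "bb_bw",
                                      "a_bb": "bb_amp", "alpha": "alpha",
                                      "loudness": "loudness"}[name]))

    if pred.n_frames != ref.n_frames:
        raise ValueError("prediction and reference disagree on frame count")
    total = None
    for name in PARAM_NAMES:
        d = (col(pred, name) - col(ref, name)) * scale[name]
        term = w[name] * (d * d).mean()
        total = term if total is None else total + term
    return total if total.requires_grad else total.item()


def autoencoder_total(S_hat, S, pred: SpeechParams, ref_f0, ref_formants,
                      w: LossWeights = None, voiced_mask=None):
    """Auto-encoder objective: ``L_MSS + l1*L_STOI + l2*L_supervision``
    with ``L_STOI = -STOI+``."""
    w = w or LossWeights()
    total = (mss_loss(S_hat, S)
             + w.lambda1 * (-as_tensor(stoi_plus(S_hat, S)))
             + w.lambda2 * as_tensor(supervision_loss(pred, ref_f0, ref_formants,
                                                      w.beta, voiced_mask)))
    return total if total.requires_grad else total.item()


def decoder_total(S_hat, S, pred: SpeechParams, ref_f0, ref_formants,
                  guidance: SpeechParams, w: LossWeights = None,
                  voiced_mask=None):
    """Decoder objective: auto-encoder terms plus ``l3 * L_reference``
    against the guidance parameters."""
    w = w or LossWeights()
    total = (as_tensor(autoencoder_total(S_hat, S, pred, ref_f0, ref_formants,
                                         w, voiced_mask))
             + w.lambda3 * as_tensor(reference_loss(pred, guidance, w.reference)))
    return total if total.requires_grad else total.item()
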