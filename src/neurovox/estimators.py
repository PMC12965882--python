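"""Pluggable pitch/formant estimation from waveforms.

When training the auto-encoder on recorded audio, the supervision series
(pitch and first four formant frequencies) come from an estimator with the
interface below; synthetic data bypasses estimation with ground truth. The
default implementation uses autocorrelation pitch tracking and LPC-root
formant estimation — the standard lightweight signal-processing recipe.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .types import FRAME_RATE

__all__ = ["PitchFormantEstimator", "AutocorrLpcEstimator"]


class PitchFormantEstimator:
    """Interface: waveform -> per-frame (f0, formants) series at 125 Hz."""

    def __call__(self, wav: np.ndarray, sr: int):
        raise NotImplementedError


def _lpc_coeffs(frame: np.ndarray, order: int) -> np.ndarray:
    """LPC by the autocorrelation method (Levinson–Durbin)."""
    r = np.correlate(frame, frame, mode="full")[len(frame) - 1:len(frame) + order]
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0] if r[0] > 0 else 1.0
    for i in range(1, order + 1):
        acc = r[i] + np.dot(a[1:i], r[1:i][::-1])
        k = -acc / err
        a[1:i + 1] = np.concatenate([a[1:i] + k * a[1:i][::-1], [k]])
        err *= (1.0 - k * k)
        if err <= 0:
            break
    return a


class AutocorrLpcEstimator(PitchFormantEstimator):
    """Autocorrelation pitch + LPC-root formants.

    Pitch: per-frame normalized autocorrelation peak within the candidate
    lag range; frames whose peak falls below ``voicing_threshold`` get f0=0.
    Formants: roots of the LPC polynomial (pre-emphasized frame), keeping
    positive-frequency roots with moderate bandwidth, sorted ascending.
    """

    def __init__(self, f0_range=(50.0, 400.0), frame_len: float = 0.04,
                 lpc_order: int = 12, voicing_threshold: float = 0.3,
                 frame_rate: float = FRAME_RATE):
        self.f0_range = f0_range
        self.frame_len = frame_len
        self.lpc_order = lpc_order
        self.voicing_threshold = voicing_threshold
        self.frame_rate = frame_rate

    def __call__(self, wav: np.ndarray, sr: int):
        wav = np.asarray(wav, dtype=np.float64)
        hop = int(round(sr / self.frame_rate))
        win = int(round(self.frame_len * sr))
        n_frames = max(1, 1 + (len(wav) - win) // hop) if len(wav) >= win else 1
        f0 = np.zeros(n_frames)
        formants = np.zeros((n_frames, 4))
        lag_min = int(sr / self.f0_range[1])
        lag_max = int(sr / self.f0_range[0])
        pre = lfilter([1.0, -0.97], [1.0], wav)
        hann = np.hanning(win)
        for m in range(n_frames):
            seg = wav[m * hop:m * hop + win]
            if len(seg) < win:
                seg = np.pad(seg, (0, win - len(seg)))
            seg = seg - seg.mean()
            ac = np.correlate(seg, seg, mode="full")[win - 1:]
            if ac[0] > 0:
                ac = ac / ac[0]
                lo, hi = lag_min, min(lag_max, win - 1)
                if hi > lo:
                    peak = lo + int(np.argmax(ac[lo:hi]))
                    if ac[peak] >= self.voicing_threshold:
                        f0[m] = sr / peak
            pseg = pre[m * hop:m * hop + win]
            if len(pseg) < win:
                pseg = np.pad(pseg, (0, win - len(pseg)))
            pseg = pseg * hann
            if np.abs(pseg).max() < 1e-8:
                continue
            a = _lpc_coeffs(pseg, self.lpc_order)
            roots = np.roots(a)
            roots = roots[np.imag(roots) > 0.01]
            freqs = np.angle(roots) * sr / (2 * np.pi)
            bws = -0.5 * sr / np.pi * np.log(np.abs(roots))
            cand = np.sort(freqs[(freqs > 90) & (bws < 600)])
            formants[m, :min(4, len(cand))] = cand[:4]
        return f0, formants
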