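"""ECoG preprocessing: common average referencing, high-gamma envelope
extraction, and z-scoring to pre-trial silent baselines.

The chain mirrors standard offline high-gamma pipelines: (optional)
polyphase downsampling of the raw clinical recording, subtraction of the
scalar common-average reference, a zero-phase 4th-order Butterworth
band-pass to 70-150 Hz, Hilbert-transform envelope, resampling to
125 frames/s onto the electrode grid, and per-electrode z-scoring against
the averaged 250 ms silent periods of the training trials. Zero-phase
filtering is appropriate here because preprocessing is offline; causality
constraints concern the decoder, not this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, hilbert, resample_poly, sosfiltfilt

from .types import FRAME_RATE, ECoGTensor

__all__ = ["RawECoG", "downsample_raw", "common_average_reference",
           "high_gamma_envelope", "zscore_to_baseline"]

HIGH_GAMMA_BAND = (70.0, 150.0)


@dataclass
class RawECoG:
    """Multichannel raw recording with electrode-grid metadata."""

    samples: np.ndarray            # (channels, time), microvolts
    fs: float                      # Hz
    channel_grid: np.ndarray       # (channels, 2) (row, col) per channel
    bad_channels: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.channel_grid = np.asarray(self.channel_grid, dtype=int)
        if self.fs <= 300:
            raise ValueError("sampling rate must exceed 300 Hz to resolve 150 Hz")
        coords = {tuple(rc) for rc in self.channel_grid}
        if len(coords) != len(self.channel_grid):
            raise ValueError("electrode grid coordinates must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    def valid_channels(self) -> np.ndarray:
        mask = np.ones(self.n_channels, dtype=bool)
        mask[list(self.bad_channels)] = False
        return mask


def downsample_raw(x: RawECoG, target_fs: float = 512.0) -> RawECoG:
    """Anti-aliased polyphase resampling (e.g. 2048 -> 512 Hz)."""
    from fractions import Fraction
    frac = Fraction(int(round(target_fs)), int(round(x.fs))).limit_denominator(1000)
    out = resample_poly(x.samples, frac.numerator, frac.denominator, axis=1)
    return RawECoG(out, target_fs, x.channel_grid, list(x.bad_channels))


def common_average_reference(x: RawECoG) -> RawECoG:
    """Subtract the scalar mean over all valid channels and all time."""
    valid = x.valid_channels()
    if not valid.any():
        raise ValueError("no valid channels left for referencing")
    car = x.samples[valid].mean()
    out = x.samples.copy()
    out[valid] = out[valid] - car
    return RawECoG(out, x.fs, x.channel_grid, list(x.bad_channels))


def band_pass_sos(fs: float, band=HIGH_GAMMA_BAND, order: int = 4):
    """4th-order Butterworth band-pass in second-order sections."""
    return butter(order, band, btype="bandpass", fs=fs, output="sos")


def high_gamma_envelope(x: RawECoG, band=HIGH_GAMMA_BAND,
                        out_rate: float = FRAME_RATE) -> ECoGTensor:
    """Band-pass to 70-150 Hz, Hilbert envelope, resample to 125 frames/s,
    and arrange channels on the electrode grid.

    Rejected channels appear as zeros with the validity mask cleared.
    """
    if x.fs < 2 * band[1]:
        raise ValueError("sampling rate too low for the high-gamma band")
    sos = band_pass_sos(x.fs, band)
    filtered = sosfiltfilt(sos, x.samples, axis=1)
    env = np.abs(hilbert(filtered, axis=1))
    from fractions import Fraction
    frac = Fraction(int(round(out_rate * 1000)),
                    int(round(x.fs * 1000))).limit_denominator(10000)
    env = resample_poly(env, frac.numerator, frac.denominator, axis=1)
    T = env.shape[1]
    H = x.channel_grid[:, 0].max() + 1
    W = x.channel_grid[:, 1].max() + 1
    grid = np.zeros((T, H, W))
    mask = np.zeros((H, W), dtype=bool)
    valid = x.valid_channels()
    for ch, (r, c) in enumerate(x.channel_grid):
        if valid[ch]:
            grid[:, r, c] = env[ch]
            mask[r, c] = True
    return ECoGTensor(grid, frame_rate=out_rate, valid_mask=mask)


def zscore_to_baseline(env: ECoGTensor, baselines) -> ECoGTensor:
    """Z-score each electrode against averaged silent-period statistics.

    ``baselines`` is a sequence of (frames, rows, cols) arrays — one silent
    window per training trial (e.g. the 250 ms before the stimulus). The
    reference mean and variance are computed per electrode over the pooled
    windows.
    """
    baselines = [np.asarray(b, dtype=np.float64) for b in baselines]
    if not baselines or any(b.size == 0 for b in baselines):
        raise ValueError("baseline windows must be nonempty")
    pooled = np.concatenate(baselines, axis=0)
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    if np.any(sd[env.valid_mask] < 1e-12):
        raise ValueError("zero baseline variance on a valid electrode")
    sd = np.where(sd < 1e-12, 1.0, sd)
    out = (env.values - mu) / sd
    out[:, ~env.valid_mask] = 0.0
    return ECoGTensor(out, frame_rate=env.frame_rate, valid_mask=env.valid_mask)
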