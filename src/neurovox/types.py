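"""Core data containers shared across the package.

Conventions: spectrograms are ``frames x K`` nonnegative magnitude arrays at
125 frames/s covering [0, 8000] Hz; ECoG tensors are ``frames x rows x cols``
z-scored high-gamma envelopes at the same frame rate; speech-parameter
trajectories carry exactly 18 scalars per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, stack

FRAME_RATE = 125.0          # frames per second of all trajectories
F_MAX = 8000.0              # Hz; half the 16 kHz audio sampling rate
N_FORMANTS = 6
N_SPEECH_PARAMS = 18
BB_BW_MIN = 2000.0          # Hz; broadband unvoice bandwidth floor

#: canonical ordering of the 18 per-frame synthesizer controls
PARAM_NAMES = (
    ["f0"]
    + [f"f{i}" for i in range(1, N_FORMANTS + 1)]
    + [f"a{i}" for i in range(1, N_FORMANTS + 1)]
    + ["f_bb", "b_bb", "a_bb", "alpha", "loudness"]
)


def _as_np(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


@dataclass
class SpeechParams:
    """Per-frame synthesizer controls (18 scalars per frame).

    Fields may hold numpy arrays (data) or autodiff ``Tensor``s (model
    outputs); the synthesizer accepts either.
    """

    f0: object                 # (T,) pitch, Hz
    formant_freq: object       # (T, 6) centre frequencies, Hz
    formant_amp: object        # (T, 6) amplitudes, >= 0
    bb_freq: object            # (T,) broadband unvoice centre frequency, Hz
    bb_bw: object              # (T,) broadband bandwidth, Hz (> 2000)
    bb_amp: object             # (T,) broadband amplitude, >= 0
    alpha: object              # (T,) voice weight in [0, 1]
    loudness: object           # (T,) >= 0

    @property
    def n_frames(self) -> int:
        return _as_np(self.f0).shape[0]

    def validate(self):
        f0 = _as_np(self.f0)
        T = f0.shape[0]
        ff, fa = _as_np(self.formant_freq), _as_np(self.formant_amp)
        bbf, bbb, bba = _as_np(self.bb_freq), _as_np(self.bb_bw), _as_np(self.bb_amp)
        al, ld = _as_np(self.alpha), _as_np(self.loudness)
        if ff.shape != (T, N_FORMANTS) or fa.shape != (T, N_FORMANTS):
            raise ValueError("formant series must be (T, 6)")
        for arr, name in [(bbf, "bb_freq"), (bbb, "bb_bw"), (bba, "bb_amp"),
                          (al, "alpha"), (ld, "loudness")]:
            if arr.shape != (T,):
                raise ValueError(f"{name} must share the frame count T={T}")
        if np.any(f0 < 0) or np.any(f0 > F_MAX):
            raise ValueError("f0 out of [0, f_max]")
        if np.any(ff < 0) or np.any(ff > F_MAX) or np.any(bbf < 0) or np.any(bbf > F_MAX):
            raise ValueError("frequency out of [0, f_max]")
        if np.any(bbb <= BB_BW_MIN):
            raise ValueError("broadband bandwidth must exceed 2000 Hz")
        if np.any(al < 0) or np.any(al > 1):
            raise ValueError("alpha out of [0, 1]")
        if np.any(fa < 0) or np.any(bba < 0) or np.any(ld < 0):
            raise ValueError("amplitudes and loudness must be nonnegative")
        return self

    def as_array(self) -> np.ndarray:
        """(T, 18) array in :data:`PARAM_NAMES` order."""
        cols = ([_as_np(self.f0)[:, None], _as_np(self.formant_freq),
                 _as_np(self.formant_amp), _as_np(self.bb_freq)[:, None],
                 _as_np(self.bb_bw)[:, None], _as_np(self.bb_amp)[:, None],
                 _as_np(self.alpha)[:, None], _as_np(self.loudness)[:, None]])
        return np.concatenate(cols, axis=1)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SpeechParams":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != N_SPEECH_PARAMS:
            raise ValueError("expected a (T, 18) array")
        return cls(
            f0=arr[:, 0],
            formant_freq=arr[:, 1:7],
            formant_amp=arr[:, 7:13],
            bb_freq=arr[:, 13],
            bb_bw=arr[:, 14],
            bb_amp=arr[:, 15],
            alpha=arr[:, 16],
            loudness=arr[:, 17],
        )


@dataclass
class Spectrogram:
    """Nonnegative magnitude spectrogram, ``frames x K`` over [0, f_max]."""

    values: np.ndarray
    frame_rate: float = FRAME_RATE
    f_max: float = F_MAX

    def __post_init__(self):
        if not isinstance(self.values, Tensor):
            self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def data(self) -> np.ndarray:
        return _as_np(self.values)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        """Bin centre frequencies: k * f_max / K, k = 0..K-1."""
        K = self.n_bins
        return np.arange(K) * (self.f_max / K)

    def validate(self):
        if np.any(self.data < 0):
            raise ValueError("magnitude spectrogram must be nonnegative")
        return self


@dataclass
class ECoGTensor:
    """Z-scored high-gamma envelopes on the electrode grid.

    ``values`` is ``frames x rows x cols``; ``valid_mask`` marks electrodes
    retained after artefact rejection (False = rejected).
    """

    values: np.ndarray
    frame_rate: float = FRAME_RATE
    valid_mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("ECoG tensor must be frames x rows x cols")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape[1:], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ECoG tensor contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self):
        return self.values.shape[1:]
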