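"""HDF5/WAV serialization for the package's containers and model states."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .types import F_MAX, FRAME_RATE, ECoGTensor, SpeechParams, Spectrogram

__all__ = ["save_speech_params", "load_speech_params", "save_spectrogram",
           "load_spectrogram", "save_ecog", "load_ecog", "save_checkpoint",
           "load_checkpoint", "write_wav", "read_wav"]


def save_speech_params(path, params: SpeechParams, mode: str = "w"):
    with h5py.File(path, mode) as f:
        g = f.require_group("params")
        g.create_dataset("f0", data=np.asarray(params.f0, dtype=np.float64))
        g.create_dataset("formant_f", data=np.asarray(params.formant_freq))
        g.create_dataset("formant_a", data=np.asarray(params.formant_amp))
        g.create_dataset("bb_f", data=np.asarray(params.bb_freq))
        g.create_dataset("bb_b", data=np.asarray(params.bb_bw))
        g.create_dataset("bb_a", data=np.asarray(params.bb_amp))
        g.create_dataset("alpha", data=np.asarray(params.alpha))
        g.create_dataset("loudness", data=np.asarray(params.loudness))
        g.attrs["frame_rate"] = FRAME_RATE


def load_speech_params(path) -> SpeechParams:
    with h5py.File(path, "r") as f:
        g = f["params"]
        return SpeechParams(
            f0=g["f0"][:], formant_freq=g["formant_f"][:],
            formant_amp=g["formant_a"][:], bb_freq=g["bb_f"][:],
            bb_bw=g["bb_b"][:], bb_amp=g["bb_a"][:],
            alpha=g["alpha"][:], loudness=g["loudness"][:])


def save_spectrogram(path, spec: Spectrogram, mode: str = "w"):
    with h5py.File(path, mode) as f:
        d = f.create_dataset("spectrogram", data=spec.data)
        d.attrs["frame_rate"] = spec.frame_rate
        d.attrs["f_max"] = spec.f_max


def load_spectrogram(path) -> Spectrogram:
    with h5py.File(path, "r") as f:
        d = f["spectrogram"]
        return Spectrogram(d[:], frame_rate=float(d.attrs.get("frame_rate", FRAME_RATE)),
                           f_max=float(d.attrs.get("f_max", F_MAX)))


def save_ecog(path, ecog: ECoGTensor, mode: str = "w"):
    with h5py.File(path, mode) as f:
        d = f.create_dataset("ecog", data=ecog.values)
        f.create_dataset("valid_mask", data=ecog.valid_mask)
        d.attrs["frame_rate"] = ecog.frame_rate


def load_ecog(path) -> ECoGTensor:
    with h5py.File(path, "r") as f:
        return ECoGTensor(f["ecog"][:],
                          frame_rate=float(f["ecog"].attrs.get("frame_rate", FRAME_RATE)),
                          valid_mask=f["valid_mask"][:].astype(bool))


def save_checkpoint(path, state_dict: dict, meta: dict = None):
    """Model state (flat name -> array) plus a JSON metadata attribute."""
    with h5py.File(path, "w") as f:
        g = f.create_group("state")
        for name, arr in state_dict.items():
            g.create_dataset(name, data=np.asarray(arr))
        f.attrs["meta"] = json.dumps(meta or {})


def load_checkpoint(path):
    with h5py.File(path, "r") as f:
        state = {name: f["state"][name][:] for name in f["state"]}
        meta = json.loads(f.attrs.get("meta", "{}"))
    return state, meta


def load_trial_dir(path):
    """Load a directory written by ``neurovox simulate`` into trial dicts."""
    from pathlib import Path
    trials = []
    root = Path(path)
    for pfile in sorted(root.glob("trial*_params.h5")):
        stem = pfile.name[:-len("_params.h5")]
        params = load_speech_params(pfile)
        trial = {"params": params, "guidance": params,
                 "f0": np.asarray(params.f0),
                 "formants": np.asarray(params.formant_freq)[:, :4],
                 "voiced": np.asarray(params.alpha) > 0.5}
        spec_file = root / f"{stem}_spec.h5"
        if spec_file.exists():
            trial["spectrogram"] = load_spectrogram(spec_file)
        ecog_file = root / f"{stem}_ecog.h5"
        if ecog_file.exists():
            trial["ecog"] = load_ecog(ecog_file)
        trials.append(trial)
    if not trials:
        raise FileNotFoundError(f"no trial files found under {path}")
    return trials


def write_wav(path, wav: np.ndarray, sr: int = 16000):
    from scipy.io import wavfile
    x = np.asarray(wav, dtype=np.float64)
    peak = np.abs(x).max()
    if peak > 1.0:
        x = x / peak
    wavfile.write(path, sr, (x * 32767).astype(np.int16))


def read_wav(path):
    from scipy.io import wavfile
    sr, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data / np.iinfo(data.dtype).max
    if data.ndim > 1:
        data = data.mean(axis=1)
    return np.asarray(data, dtype=np.float64), int(sr)
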