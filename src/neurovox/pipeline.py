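"""Experiment orchestration and evaluation.

Ties the modules into the two-step protocol: (1) speech-to-speech
auto-encoder pre-training learns the speaker parameters and a speech
encoder whose outputs become the reference ("guidance") trajectories;
(2) the ECoG decoder is trained against those references plus the
spectrogram losses; evaluation reports spectrogram PCC, STOI+, and
per-parameter PCCs on held-out trials.

Pitch and formant PCCs are computed over voiced frames (ground-truth voice
weight > 0.5) because those trajectories are physically undefined in
unvoiced spans; voice weight and loudness use all frames.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import stoi_plus
from .occlusion import contribution_map, noise_floor_map, spectrogram_pcc
from .synth import synthesize
from .types import SpeechParams

__all__ = ["pcc", "parameter_pccs", "evaluate", "run_experiment",
           "default_config", "word_level_split"]


def pcc(a, b) -> float:
    a, b = np.ravel(a), np.ravel(b)
    if a.std() < 1e-12 or b.std() < 1e-12:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def parameter_pccs(pred: SpeechParams, ref: SpeechParams,
                   voiced_threshold: float = 0.5) -> dict:
    """PCCs for the headline parameters of one trial."""
    voiced = np.asarray(ref.alpha) > voiced_threshold
    out = {"alpha": pcc(pred.alpha, ref.alpha),
           "loudness": pcc(pred.loudness, ref.loudness)}
    if voiced.sum() >= 3:
        out["f0"] = pcc(np.asarray(pred.f0)[voiced], np.asarray(ref.f0)[voiced])
        for i in (0, 1):
            out[f"f{i + 1}"] = pcc(np.asarray(pred.formant_freq)[voiced, i],
                                   np.asarray(ref.formant_freq)[voiced, i])
    return out


def evaluate(predict_fn, speaker, test_set, seed: int = 0,
             voiced_threshold: float = 0.5) -> dict:
    """Evaluate a parameter predictor on held-out trials.

    ``predict_fn`` maps a trial dict to a :class:`SpeechParams` (an ECoG
    decoder consuming ``trial['ecog']`` or a speech encoder consuming
    ``trial['spectrogram']``). Returns per-trial rows, their means, and
    pooled voiced-frame parameter PCCs across all test trials.
    """
    if len(test_set) == 0:
        raise ValueError("empty test set")
    rows = []
    pools = {k: ([], []) for k in ("f0", "f1", "f2", "alpha", "loudness")}
    for k, tr in enumerate(test_set):
        pred_t = predict_fn(tr)
        pred = SpeechParams.from_array(pred_t.as_array())
        S_hat = synthesize(pred, speaker, seed=None)   # mean-field noise
        row = {"trial": k,
               "spectrogram_pcc": spectrogram_pcc(S_hat, tr["spectrogram"]),
               "stoi_plus": stoi_plus(S_hat, tr["spectrogram"])}
        ref = tr["params"]
        row.update(parameter_pccs(pred, ref, voiced_threshold))
        rows.append(row)
        voiced = np.asarray(ref.alpha) > voiced_threshold
        pools["f0"][0].append(np.asarray(pred.f0)[voiced])
        pools["f0"][1].append(np.asarray(ref.f0)[voiced])
        for i in (0, 1):
            pools[f"f{i + 1}"][0].append(np.asarray(pred.formant_freq)[voiced, i])
            pools[f"f{i + 1}"][1].append(np.asarray(ref.formant_freq)[voiced, i])
        pools["alpha"][0].append(np.asarray(pred.alpha))
        pools["alpha"][1].append(np.asarray(ref.alpha))
        pools["loudness"][0].append(np.asarray(pred.loudness))
        pools["loudness"][1].append(np.asarray(ref.loudness))
    table = pd.DataFrame(rows)
    pooled = {k: pcc(np.concatenate(v[0]), np.concatenate(v[1]))
              for k, v in pools.items()}
    means = table.drop(columns="trial").mean(numeric_only=True).to_dict()
    return {"per_trial": table, "mean": means, "pooled_param_pcc": pooled}


def word_level_split(trials, test_fraction: float = 1 / 8, seed: int = 0):
    """Train/test split over unique word ids (held-out words never seen in
    training)."""
    words = sorted({tr["word_id"] for tr in trials})
    if len(words) < 2:
        raise ValueError("word-level split needs at least two unique words")
    rng = np.random.default_rng(seed)
    n_test = min(max(1, int(round(len(words) * test_fraction))), len(words) - 1)
    test_words = set(rng.permutation(words)[:n_test].tolist())
    train_idx = [i for i, tr in enumerate(trials) if tr["word_id"] not in test_words]
    test_idx = [i for i, tr in enumerate(trials) if tr["word_id"] in test_words]
    return np.asarray(train_idx), np.asarray(test_idx), sorted(test_words)


def default_config() -> dict:
    return {
        "seed": 0,
        "n_trials": 60,
        "n_words": None,             # default: one word per ~8 trials
        "split": "trial",            # "trial" | "word"
        "spec": {"duration_s": 0.5, "n_segments": 3, "voiced_fraction": 0.7,
                 "grid": [4, 4], "profile": "female"},
        "mapping": {"noise_sd": 0.1, "kind": "dense"},
        "autoencoder": {"steps": 150, "batch_size": 6, "width_factor": 0.5},
        "decoder": {"backbone": "lstm", "causal": True, "steps": 150,
                    "batch_size": 6, "channels": 32},
        "occlusion": {"enabled": False},
        "out_dir": None,
    }


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_experiment(config: dict = None) -> dict:
    """simulate -> train auto-encoder -> train decoder -> evaluate
    [-> occlusion]; fully reproducible from config + seeds.

    Returns the artifact dict; writes JSON/CSV artifacts when
    ``config['out_dir']`` is set. Stage failures surface with the stage
    name attached.
    """
    from dataclasses import replace as dc_replace

    from .decoders import (DecoderConfig, DecoderTrainConfig, train_decoder)
    from .encoder import EncoderConfig, TrainConfig, train_autoencoder
    from .simdata import GenerativeMapping, SynthTrialSpec, make_dataset

    cfg = default_config()
    user = config or {}
    for key, val in user.items():
        if isinstance(val, dict) and key in cfg:
            cfg[key].update(val)
        else:
            cfg[key] = val
    seed = int(cfg["seed"])
    log = []

    def stage(name):
        log.append({"stage": name})

    try:
        stage("simulate")
        spec = SynthTrialSpec(duration_s=cfg["spec"]["duration_s"],
                              n_segments=cfg["spec"]["n_segments"],
                              voiced_fraction=cfg["spec"]["voiced_fraction"],
                              grid=tuple(cfg["spec"]["grid"]),
                              profile=cfg["spec"]["profile"])
        mapping = GenerativeMapping.dense(spec.grid, seed=seed + 1,
                                          noise_sd=cfg["mapping"]["noise_sd"])
        data = make_dataset(cfg["n_trials"], spec, mapping, seed=seed,
                            n_words=cfg.get("n_words"))
        if cfg["split"] == "word":
            train_idx, test_idx, held_words = word_level_split(
                data.trials, seed=seed)
        else:
            train_idx, test_idx, held_words = data.train_idx, data.test_idx, None
        train = [data.trials[i] for i in train_idx]
        test = [data.trials[i] for i in test_idx]

        stage("train-autoencoder")
        enc_cfg = EncoderConfig().scaled(cfg["autoencoder"]["width_factor"])
        enc, speaker, ae_hist = train_autoencoder(
            train, TrainConfig(steps=cfg["autoencoder"]["steps"],
                               batch_size=cfg["autoencoder"]["batch_size"],
                               profile=spec.profile),
            enc_cfg, seed=seed + 2)

        stage("encode-guidance")
        guided = []
        for tr in train:
            g = SpeechParams.from_array(enc.encode(tr["spectrogram"]).as_array())
            guided.append({**tr, "guidance": g})

        stage("train-decoder")
        dec_cfg = DecoderConfig(backbone=cfg["decoder"]["backbone"],
                                causal=cfg["decoder"]["causal"],
                                channels=cfg["decoder"]["channels"]).toy()
        dec_cfg = dc_replace(dec_cfg, channels=cfg["decoder"]["channels"])
        dec, dec_hist = train_decoder(
            guided, speaker, dec_cfg,
            DecoderTrainConfig(steps=cfg["decoder"]["steps"],
                               batch_size=cfg["decoder"]["batch_size"]),
            seed=seed + 3)

        stage("evaluate")
        report = evaluate(lambda tr: dec(tr["ecog"]), speaker, test,
                          seed=seed + 4)

        artifacts = {
            "config": cfg, "config_hash": _config_hash(
                {k: v for k, v in cfg.items() if k != "out_dir"}),
            "manifest": data.manifest, "held_out_words": held_words,
            "ae_history": ae_hist, "decoder_history": dec_hist,
            "report_mean": report["mean"],
            "report_pooled": report["pooled_param_pcc"],
            "report_table": report["per_trial"],
            "log": log,
        }

        if cfg["occlusion"]["enabled"]:
            stage("occlusion")
            cm = contribution_map(dec, speaker, test, seed=seed + 5)
            floor = noise_floor_map(guided, test, speaker, dec_cfg,
                                    DecoderTrainConfig(
                                        steps=cfg["decoder"]["steps"],
                                        batch_size=cfg["decoder"]["batch_size"]),
                                    seed=seed + 6)
            artifacts["contribution"] = cm.contrib
            artifacts["noise_floor"] = floor.contrib
    except Exception as err:
        raise RuntimeError(f"experiment failed in stage "
                           f"{log[-1]['stage'] if log else '?'}: {err}") from err

    out_dir = cfg.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
        (out / "manifest.json").write_text(json.dumps(data.manifest, indent=2))
        artifacts["report_table"].to_csv(out / "report.csv", index=False)
        summary = {"config_hash": artifacts["config_hash"],
                   "mean": artifacts["report_mean"],
                   "pooled": artifacts["report_pooled"],
                   "final_ae_loss": ae_hist[-1],
                   "final_decoder_loss": dec_hist[-1]}
        (out / "report.json").write_text(json.dumps(summary, indent=2))
        with open(out / "log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return artifacts
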