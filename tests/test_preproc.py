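"""Preprocessing-chain tests: referencing, high-gamma envelope, z-scoring."""

import numpy as np
import pytest
from scipy.signal import sosfreqz

from neurovox.preproc import (RawECoG, band_pass_sos, common_average_reference,
                              downsample_raw, high_gamma_envelope,
                              zscore_to_baseline)
from neurovox.types import ECoGTensor


def _grid(n):
    return np.array([(i // 4, i % 4) for i in range(n)])


def make_raw(samples, fs=512.0, bad=()):
    return RawECoG(samples, fs, _grid(samples.shape[0]), list(bad))


# -- common average reference ------------------------------------------------

def test_car_constant_recording_becomes_zero():
    raw = make_raw(np.full((4, 100), 7.3))
    out = common_average_reference(raw)
    assert np.abs(out.samples).max() < 1e-12


def test_car_zero_mean_recording_unchanged():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(4, 200))
    x -= x.mean()
    out = common_average_reference(make_raw(x.copy()))
    np.testing.assert_allclose(out.samples, x, atol=1e-12)


def test_car_two_channel_arithmetic():
    x = np.vstack([np.ones(50), 3 * np.ones(50)])
    out = common_average_reference(make_raw(x))
    np.testing.assert_allclose(out.samples, x - 2.0)


def test_car_ignores_bad_channels_and_rejects_all_bad():
    x = np.vstack([np.ones(50), 100 * np.ones(50)])
    out = common_average_reference(make_raw(x, bad=[1]))
    np.testing.assert_allclose(out.samples[0], 0.0)       # mean from ch0 only
    with pytest.raises(ValueError):
        common_average_reference(make_raw(x, bad=[0, 1]))


# -- high-gamma envelope -----------------------------------------------------

def test_envelope_of_in_band_tone_recovers_amplitude():
    fs, A = 512.0, 2.5
    t = np.arange(int(fs * 4)) / fs
    x = A * np.sin(2 * np.pi * 100.0 * t)
    env = high_gamma_envelope(make_raw(np.tile(x, (2, 1)), fs))
    mid = env.values[20:-20, 0, 0]
    assert np.median(mid) == pytest.approx(A, rel=0.05)
    assert env.frame_rate == 125


def test_envelope_rejects_out_of_band_tone():
    fs = 512.0
    t = np.arange(int(fs * 4)) / fs
    x = 2.0 * np.sin(2 * np.pi * 10.0 * t)
    env = high_gamma_envelope(make_raw(np.tile(x, (1, 1)), fs))
    assert np.median(env.values[20:-20, 0, 0]) < 0.05


def test_raw_recording_rejects_low_sampling_rate():
    with pytest.raises(ValueError):
        make_raw(np.zeros((1, 1000)), fs=250.0)
    with pytest.raises(ValueError):
        high_gamma_envelope(make_raw(np.zeros((1, 1000)), fs=310.0),
                            band=(70.0, 200.0))


def test_band_pass_attenuation_spec():
    sos = band_pass_sos(512.0)
    for f_test in (35.0, 250.0):
        w, h = sosfreqz(sos, worN=[f_test], fs=512.0)
        # forward-backward filtering doubles the dB attenuation
        att_db = -20 * np.log10(max(abs(h[0]) ** 2, 1e-12))
        assert att_db >= 20.0, f_test


def test_downsample_preserves_content():
    fs = 2048.0
    t = np.arange(int(fs)) / fs
    x = np.sin(2 * np.pi * 100.0 * t)
    out = downsample_raw(make_raw(np.tile(x, (1, 1)), fs), 512.0)
    assert out.fs == 512.0
    assert out.samples.shape[1] == 512
    spec = np.abs(np.fft.rfft(out.samples[0]))
    freqs = np.fft.rfftfreq(512, 1 / 512.0)
    assert abs(freqs[np.argmax(spec)] - 100.0) < 2.0


# -- baseline z-scoring ------------------------------------------------------

def test_zscore_matches_baseline_statistics():
    rng = np.random.default_rng(1)
    mu, sd = 3.0, 2.0
    base = [rng.normal(mu, sd, size=(2500, 2, 2)) for _ in range(4)]
    env = ECoGTensor(rng.normal(mu, sd, size=(5000, 2, 2)))
    out = zscore_to_baseline(env, base)
    assert abs(out.values.mean()) < 0.05
    assert abs(out.values.std() - 1.0) < 0.05


def test_zscore_of_baseline_mean_is_zero():
    base = [np.full((100, 2, 2), 5.0) + np.random.default_rng(0).normal(
        0, 1.0, (100, 2, 2))]
    mu = base[0].mean(axis=0)
    env = ECoGTensor(np.tile(mu, (30, 1, 1)))
    out = zscore_to_baseline(env, base)
    assert np.abs(out.values).max() < 1e-10


def test_zscore_idempotent_for_standard_baseline():
    rng = np.random.default_rng(3)
    big = rng.normal(0, 1, (20000, 1, 1))
    env = ECoGTensor(rng.normal(0, 1, (50, 1, 1)))
    once = zscore_to_baseline(env, [big])
    assert np.abs(once.values - env.values).max() < 0.05


def test_zscore_rejects_flat_baseline():
    env = ECoGTensor(np.zeros((10, 1, 1)))
    with pytest.raises(ValueError):
        zscore_to_baseline(env, [np.full((50, 1, 1), 2.0)])


def test_pipeline_deterministic():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(3, 2048))
    raw = make_raw(x, 512.0)
    a = high_gamma_envelope(common_average_reference(raw))
    b = high_gamma_envelope(common_average_reference(raw))
    np.testing.assert_array_equal(a.values, b.values)
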