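"""Synthesizer unit tests: filters, excitations, mixing, counts, gradients."""

import numpy as np
import pytest

from neurovox import synth
from neurovox.autodiff import Tensor
from neurovox.synth import (InvalidParameterError, SpeakerParams,
                            bandwidth_from_center, count_learnable_params,
                            formant_filter_response, harmonic_excitation,
                            noise_excitation, prototype_filter_eval,
                            prototype_peak_bandwidth, pwl_interp,
                            spectrogram_to_waveform, synthesize,
                            unvoice_component, voice_component,
                            waveform_to_spectrogram)
from neurovox.types import F_MAX, SpeechParams, Spectrogram

from conftest import flat_params


# -- bandwidth relation ------------------------------------------------------

@pytest.mark.parametrize("f_c,expected", [(400.0, 100.0), (500.0, 100.0),
                                          (1500.0, 300.0)])
def test_bandwidth_piecewise_evaluation(f_c, expected):
    assert bandwidth_from_center(f_c, (500.0, 0.2, 100.0)) == pytest.approx(expected)


def test_bandwidth_continuous_at_threshold():
    below = bandwidth_from_center(500.0 - 1e-9, (500.0, 0.2, 100.0))
    above = bandwidth_from_center(500.0 + 1e-9, (500.0, 0.2, 100.0))
    assert abs(above - below) < 1e-6


def test_bandwidth_invalid_baseline_rejected():
    with pytest.raises(InvalidParameterError):
        bandwidth_from_center(400.0, (500.0, 0.2, -1.0))
    with pytest.raises(InvalidParameterError):
        bandwidth_from_center(5000.0, (500.0, -1.0, 100.0))


# -- prototype filters -------------------------------------------------------

def _triangle(M=80, peak=30, half=10):
    g = np.clip(1.0 - np.abs(np.arange(M) - peak) / half, 0.0, None)
    return g


def test_prototype_interpolation_passes_through_samples():
    g = _triangle()
    grid = np.linspace(0, F_MAX, len(g))
    vals = prototype_filter_eval(g, grid)
    np.testing.assert_allclose(np.asarray(vals.data), g, atol=1e-12)


def test_prototype_half_power_bandwidth_matches_dense_scan():
    g = _triangle()
    _, b_proto = prototype_peak_bandwidth(g)
    dense = np.linspace(0, F_MAX, 200001)
    gains = np.interp(dense, np.linspace(0, F_MAX, len(g)), g)
    span = dense[gains >= 1 / np.sqrt(2)]
    assert b_proto == pytest.approx(span[-1] - span[0], abs=2 * F_MAX / 200000)


def test_prototype_out_of_range_clamps_to_endpoints():
    g = _triangle()
    vals = pwl_interp(g, np.array([-500.0, F_MAX + 500.0]))
    np.testing.assert_allclose(vals.data, [g[0], g[-1]])


def test_prototype_rejects_non_unimodal_samples():
    g = _triangle()
    g[10] = 0.9     # spurious second peak
    with pytest.raises(InvalidParameterError):
        prototype_filter_eval(g, np.array([100.0]))


# -- formant filter (shift/scale of the prototype) ---------------------------

def _gauss_proto(M=80, c=40, w=8):
    g = np.exp(-0.5 * ((np.arange(M) - c) / w) ** 2)
    return g / g.max()


def test_formant_filter_zero_amplitude_is_zero():
    f = np.linspace(0, F_MAX, 257)
    resp = formant_filter_response(_gauss_proto(), 1000.0, 200.0, 0.0, f)
    assert np.all(resp == 0)


def test_formant_filter_identity_when_unshifted():
    g = _gauss_proto()
    f_proto, b_proto = prototype_peak_bandwidth(g)
    f = np.linspace(0, F_MAX, 257)
    resp = formant_filter_response(g, f_proto, b_proto, 2.0, f)
    expected = 2.0 * np.asarray(pwl_interp(g, f).data)
    np.testing.assert_allclose(resp, expected, atol=1e-10)


def test_formant_filter_symmetry_about_center():
    # symmetric prototype: equal gains equidistant from the centre frequency
    f = np.array([900.0, 1100.0])
    resp = formant_filter_response(_gauss_proto(), 1000.0, 200.0, 1.0, f)
    assert resp[0] == pytest.approx(resp[1], rel=1e-9)


def test_formant_filter_peak_and_width():
    f = np.linspace(0, F_MAX, 8001)
    resp = formant_filter_response(_gauss_proto(), 1000.0, 200.0, 1.5, f)
    assert f[np.argmax(resp)] == pytest.approx(1000.0, abs=f[1] - f[0])
    assert resp.max() == pytest.approx(1.5, rel=1e-6)
    span = f[resp >= 1.5 / np.sqrt(2)]
    assert span[-1] - span[0] == pytest.approx(200.0, rel=0.02)


def test_formant_filter_rejects_nonpositive_bandwidth():
    with pytest.raises(InvalidParameterError):
        formant_filter_response(_gauss_proto(), 1000.0, -5.0, 1.0,
                                np.array([100.0]))


# -- harmonic excitation -----------------------------------------------------

def test_harmonic_peaks_at_multiples_of_f0():
    K = 256
    H = harmonic_excitation(np.full(3, 250.0), K).data
    df = F_MAX / K
    row = H[1]
    peaks = np.where((row[1:-1] > row[:-2]) & (row[1:-1] > row[2:]))[0] + 1
    expected = np.rint(250.0 * np.arange(1, 33) / df).astype(int)
    assert set(expected[:10]).issubset(set(peaks))


def test_harmonics_above_fmax_are_removed():
    # f0 = 900 Hz: only k <= 8 fits below 8 kHz; no aliased energy above
    K = 256
    df = F_MAX / K
    row = harmonic_excitation(np.full(2, 900.0), K).data[0]
    cutoff = int(np.rint(900.0 * 8 / df)) + 10
    assert row[cutoff:].max() < 1e-6
    assert row[int(np.rint(900.0 * 8 / df))] > 0.5


def test_harmonic_zero_pitch_is_silent():
    H = harmonic_excitation(np.zeros(4), 128).data
    assert np.all(H == 0)


def test_harmonic_peak_tracks_rising_pitch():
    f0 = np.linspace(150.0, 350.0, 20)
    H = harmonic_excitation(f0, 512).data
    df = F_MAX / 512
    for t in range(20):
        # fundamental is the largest peak below the second harmonic
        band = H[t, :int(1.5 * f0[t] / df)]
        assert abs(np.argmax(band) * df - f0[t]) <= df


def test_harmonic_rejects_negative_pitch():
    with pytest.raises(InvalidParameterError):
        harmonic_excitation(np.array([-10.0]), 128)


# -- noise pathway -----------------------------------------------------------

def test_unvoice_zero_amplitudes_give_zero(speaker):
    p = flat_params(5, amps=np.zeros(6), bb_amp=0.0)
    U = unvoice_component(p, speaker, seed=1)
    assert np.abs(U.data).max() == 0


def test_unvoice_deterministic_given_seed(speaker, toy_params):
    a = unvoice_component(toy_params, speaker, seed=9).data
    b = unvoice_component(toy_params, speaker, seed=9).data
    np.testing.assert_array_equal(a, b)


def test_unvoice_band_energy_proportional_to_filter_power(speaker):
    p = flat_params(2)
    U2 = np.mean([unvoice_component(p, speaker, seed=s).data ** 2
                  for s in range(200)], axis=0)
    # expected E[U^2] = |F_u|^2 * E[N^2] with E[N^2] = 1
    F = unvoice_component(p, speaker, seed=None).data / (np.sqrt(np.pi) / 2)
    strong = F[0] > 0.1
    ratio = U2[0][strong] / F[0][strong] ** 2
    assert abs(np.mean(ratio) - 1.0) < 0.15


def test_unvoice_rejects_narrow_broadband(speaker):
    p = flat_params(3)
    p.bb_bw = np.full(3, 1500.0)
    with pytest.raises(InvalidParameterError):
        unvoice_component(p, speaker, seed=0)


# -- full synthesis ----------------------------------------------------------

def test_mix_alpha_one_is_pure_voice(speaker):
    p = flat_params(6, alpha=1.0)
    S = synthesize(p, speaker, seed=2).data
    V = voice_component(p, speaker).data
    B = speaker.background().data
    np.testing.assert_allclose(S, p.loudness[:, None] * V + B, atol=1e-12)


def test_zero_loudness_leaves_background(speaker):
    p = flat_params(6, loudness=0.0)
    S = synthesize(p, speaker, seed=2).data
    np.testing.assert_allclose(S, np.tile(speaker.background().data, (6, 1)),
                               atol=1e-12)


def test_mix_is_convex_at_half(speaker):
    p = flat_params(6, alpha=0.5)
    S = synthesize(p, speaker, seed=7).data
    V = voice_component(p, speaker).data
    U = unvoice_component(p, speaker, seed=7).data
    B = speaker.background().data
    np.testing.assert_allclose(S, p.loudness[:, None] * 0.5 * (V + U) + B,
                               atol=1e-10)


def test_mixing_identity_alpha_extremes(speaker, toy_params):
    p1 = flat_params(8, alpha=1.0)
    p0 = flat_params(8, alpha=0.0)
    B = speaker.background().data
    lhs = (synthesize(p1, speaker, seed=4).data
           + synthesize(p0, speaker, seed=4).data - 2 * B)
    V = voice_component(p1, speaker).data
    U = unvoice_component(p0, speaker, seed=4).data
    np.testing.assert_allclose(lhs, p1.loudness[:, None] * (V + U), atol=1e-9)


def test_output_dominates_background(speaker, toy_params):
    S = synthesize(toy_params, speaker, seed=3).data
    B = speaker.background().data
    assert np.all(S >= B[None, :] - 1e-12) and np.all(B >= 0)


def test_frame_count_mismatch_raises(speaker):
    p = flat_params(6)
    p.alpha = np.full(5, 0.5)
    with pytest.raises(ValueError):
        synthesize(p, speaker, seed=0)


# -- learnable parameter counts ---------------------------------------------

def test_learnable_parameter_totals():
    assert count_learnable_params("female") == 834
    assert count_learnable_params("male") == 1090
    assert synth.M_PROTO * (synth.N_FORMANTS + 1) == 560
    assert count_learnable_params("female") - count_learnable_params("male") == -256


def test_instantiated_speaker_matches_count():
    for profile in ("female", "male"):
        s = SpeakerParams.default(profile, seed=1)
        assert s.count_learnable() == count_learnable_params(profile)


def test_unknown_profile_rejected():
    with pytest.raises(InvalidParameterError):
        count_learnable_params("child")


def test_speaker_constraints_hold_after_perturbation(speaker):
    # gradient steps can move raw values anywhere; constraints must survive
    for t in (speaker.proto_raw, speaker.bw_raw, speaker.bg_raw):
        t.data = t.data + 0.3
    protos = speaker.prototypes().data
    for g in protos:
        synth.check_unimodal(g)
        assert g.max() == pytest.approx(1.0)
    _, slope, b0 = speaker.bw_triples()
    assert np.all(slope.data >= 0) and np.all(b0.data > 0)
    assert np.all(speaker.background().data >= 0)
    for t in (speaker.proto_raw, speaker.bw_raw, speaker.bg_raw):
        t.data = t.data - 0.3


# -- differentiability -------------------------------------------------------

def test_gradients_match_finite_differences_for_all_18_params(speaker):
    T = 5
    base = flat_params(T, alpha=0.6)
    target = synthesize(base, speaker, seed=11).data + 0.05

    fields = ["f0", "formant_freq", "formant_amp", "bb_freq", "bb_bw",
              "bb_amp", "alpha", "loudness"]

    def loss_value(params):
        S = synthesize(params, speaker, seed=11)
        d = S.data - target
        return float((d * d).sum())

    for name in fields:
        p = flat_params(T, alpha=0.6)
        leaf = Tensor(np.asarray(getattr(p, name), dtype=float).copy(),
                      requires_grad=True)
        setattr(p, name, leaf)
        S = synthesize(p, speaker, seed=11)
        d = S.values - target
        (d * d).sum().backward()
        auto = leaf.grad.copy()

        num = np.zeros_like(auto)
        base_arr = np.asarray(getattr(base, name), dtype=float)
        it = np.ndindex(*base_arr.shape)
        for idx in it:
            for sgn in (1.0, -1.0):
                q = flat_params(T, alpha=0.6)
                arr = np.asarray(getattr(q, name), dtype=float).copy()
                arr[idx] += sgn * 1e-4
                setattr(q, name, arr)
                num[idx] += sgn * loss_value(q) / 2e-4
        scale = max(np.abs(num).max(), 1e-6)
        assert np.abs(auto - num).max() / scale < 1e-3, name


# -- waveform plumbing -------------------------------------------------------

def test_griffin_lim_recovers_tone_frequency():
    K, T = 256, 50
    df = F_MAX / K
    spec = np.zeros((T, K))
    spec[:, 40] = 1.0          # 1250 Hz tone
    wav, errors = spectrogram_to_waveform(Spectrogram(spec), n_iter=20,
                                          seed=0, return_errors=True)
    freqs = np.fft.rfftfreq(len(wav), 1 / 16000)
    mag = np.abs(np.fft.rfft(wav))
    assert abs(freqs[np.argmax(mag)] - 40 * df) < 2 * df
    assert all(b <= a + 1e-6 for a, b in zip(errors, errors[1:]))


def test_griffin_lim_zero_spectrogram_is_silent():
    wav = spectrogram_to_waveform(Spectrogram(np.zeros((30, 128))), n_iter=3)
    assert np.abs(wav).max() < 1e-12


def test_waveform_spectrogram_roundtrip_shape():
    rng = np.random.default_rng(0)
    wav = rng.normal(size=16000)
    spec = waveform_to_spectrogram(wav, n_bins=256)
    assert spec.n_bins == 256
    assert abs(spec.n_frames - 125) <= 4
    spec.validate()
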