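"""Loss-stack tests: MSS, one-third-octave bands, STOI+, supervision,
reference, and the weighted totals."""

import numpy as np
import pytest

from neurovox.autodiff import Tensor
from neurovox.losses import (LossWeights, REFERENCE_WEIGHTS, autoencoder_total,
                             decoder_total, mel_filterbank, mss_loss,
                             octave_band_edges, octave_band_norms,
                             reference_loss, stoi_plus, supervision_loss)
from neurovox.types import F_MAX, SpeechParams, Spectrogram

from conftest import flat_params

RNG = np.random.default_rng(7)


# -- MSS ---------------------------------------------------------------------

def test_mss_zero_on_identical_spectrograms():
    S = Spectrogram(RNG.random((10, 64)) + 0.1)
    assert mss_loss(S, S) == 0.0


def test_mss_closed_form_for_doubled_input():
    # doubling an all-positive spectrogram: linear term = mean |S|,
    # log term = log 2 per cell; same structure on the Mel scale
    S = np.array([[1.0, 2.0, 0.5, 1.5], [0.7, 0.9, 1.1, 1.3]])
    fb = mel_filterbank(4, n_mels=3)
    M = S @ fb
    expected = (np.abs(S).mean() + np.log(2)
                + np.abs(M).mean()
                + np.count_nonzero(M > 0) * np.log(2) / M.size)
    got = mss_loss(Spectrogram(2 * S), Spectrogram(S), n_mels=3)
    assert got == pytest.approx(expected, rel=1e-9)


def test_mss_symmetric_and_positive():
    a = Spectrogram(RNG.random((8, 32)) + 0.1)
    b = Spectrogram(RNG.random((8, 32)) + 0.1)
    assert mss_loss(a, b) == pytest.approx(mss_loss(b, a))
    assert mss_loss(a, b) > 0


def test_mss_shape_mismatch_raises():
    with pytest.raises(ValueError):
        mss_loss(Spectrogram(np.ones((4, 8))), Spectrogram(np.ones((4, 9))))


# -- one-third octave bands --------------------------------------------------

def test_fifteen_bands_with_expected_edges():
    edges, centers = octave_band_edges(256)
    assert len(centers) == 15
    assert centers[0] == pytest.approx(150.0)
    assert centers[-1] * 2 ** (1 / 6) == pytest.approx(4278, rel=0.01)  # ~4.3 kHz
    assert np.all(edges[:, 1] > edges[:, 0])


def test_band_energy_of_narrow_tone_in_one_band():
    K = 512
    S = np.zeros((40, K))
    df = F_MAX / K
    tone_bin = int(round(1000.0 / df))
    S[:, tone_bin] = 2.0
    bd = octave_band_norms(Spectrogram(S))
    energies = np.asarray(bd.band_norms)[0]
    hot = np.where(energies > 1e-6)[0]
    assert len(hot) == 1
    k1, k2 = bd.band_edges[hot[0]]
    assert k1 <= tone_bin < k2


def test_band_norms_conserve_energy():
    S = RNG.random((20, 256))
    bd = octave_band_norms(Spectrogram(S))
    band_total = (np.asarray(bd.band_norms) ** 2).sum()
    lo, hi = bd.band_edges[0, 0], bd.band_edges[-1, 1]
    direct = (S[:, lo:hi] ** 2).sum()
    assert band_total <= direct + 1e-6


def test_too_coarse_spectrogram_rejected():
    with pytest.raises(ValueError):
        octave_band_edges(32)        # 250 Hz bins cannot resolve the 150 Hz band


# -- STOI+ -------------------------------------------------------------------

def test_stoi_self_similarity_is_one():
    S = Spectrogram(RNG.random((45, 256)) + 0.05)
    assert stoi_plus(S, S) == pytest.approx(1.0)


def test_stoi_affine_invariance_per_band():
    x = RNG.random((45, 256)) + 0.05
    bd = octave_band_norms(Spectrogram(x))
    # a spectrogram scaling is an affine map of every envelope segment
    assert stoi_plus(Spectrogram(3.0 * x), Spectrogram(x)) == pytest.approx(1.0)
    del bd


def test_stoi_range_and_zero_mean_for_uncorrelated_inputs():
    vals = []
    for s in range(40):
        rng = np.random.default_rng(s)
        a = Spectrogram(rng.random((40, 256)))
        b = Spectrogram(rng.random((40, 256)))
        v = stoi_plus(a, b)
        assert -1.0 <= v <= 1.0
        vals.append(v)
    assert abs(np.mean(vals)) < 0.05


def test_stoi_requires_thirty_frames():
    with pytest.raises(ValueError):
        stoi_plus(Spectrogram(np.ones((20, 256))), Spectrogram(np.ones((20, 256))))


def test_stoi_zero_variance_segments_contribute_zero():
    a = Spectrogram(np.ones((35, 256)))       # constant -> all segments flat
    b = Spectrogram(np.ones((35, 256)))
    assert stoi_plus(a, b) == 0.0


# -- supervision -------------------------------------------------------------

def test_supervision_zero_when_exact():
    p = flat_params(5)
    assert supervision_loss(p, p.f0, p.formant_freq[:, :4]) == 0.0


def test_supervision_hand_computed_f1_error():
    T, delta = 3, 10.0
    p = flat_params(T)
    ref_ff = p.formant_freq.copy()
    p2 = flat_params(T)
    p2.formant_freq = p2.formant_freq.copy()
    p2.formant_freq[:, 0] += delta
    got = supervision_loss(p2, p.f0, ref_ff[:, :4])
    assert got == pytest.approx(0.1 * delta ** 2)   # Hz, mean over frames


def test_supervision_ignores_formants_five_and_six():
    p = flat_params(4)
    p2 = flat_params(4)
    p2.formant_freq = p2.formant_freq.copy()
    p2.formant_freq[:, 4:] += 500.0
    assert supervision_loss(p2, p.f0, p.formant_freq[:, :4]) == 0.0


def test_supervision_voiced_mask_restricts_frames():
    T, delta = 4, 20.0
    p = flat_params(T)
    p2 = flat_params(T)
    p2.f0 = p2.f0 + delta
    mask = np.array([1.0, 0.0, 1.0, 0.0])
    got = supervision_loss(p2, p.f0, p.formant_freq[:, :4], voiced_mask=mask)
    assert got == pytest.approx(delta ** 2)   # mean over the 2 voiced frames


# -- reference loss ----------------------------------------------------------

def test_reference_zero_when_equal():
    p = flat_params(3)
    assert reference_loss(p, p) == 0.0


def test_reference_unit_alpha_error_weighted():
    p = flat_params(1, alpha=0.0)
    q = flat_params(1, alpha=1.0)
    assert reference_loss(q, p) == pytest.approx(1.8)   # alpha is unnormalized


def test_reference_scales_linearly_with_weights():
    p = flat_params(2)
    q = flat_params(2, alpha=0.3, loudness=2.0)
    base = reference_loss(q, p)
    doubled = reference_loss(q, p, weights={k: 2 * v for k, v in
                                            REFERENCE_WEIGHTS.items()})
    assert doubled == pytest.approx(2 * base)


def test_reference_all_18_parameters_contribute():
    p = flat_params(2)
    q = flat_params(2)
    q.bb_bw = q.bb_bw + 100.0        # bandwidth-only error must register
    assert reference_loss(q, p) > 0


# -- totals ------------------------------------------------------------------

def _pair(T=40, K=256):
    S = Spectrogram(RNG.random((T, K)) + 0.05)
    p = flat_params(T)
    return S, p


def test_autoencoder_total_perfect_case_is_minus_lambda1():
    S, p = _pair()
    total = autoencoder_total(S, S, p, p.f0, p.formant_freq[:, :4])
    assert total == pytest.approx(-1.2)    # MSS=0, supervision=0, STOI+=1


def test_autoencoder_total_reduces_to_mss_without_weights():
    S, p = _pair()
    S2 = Spectrogram(np.asarray(S.values) * 1.5)
    w = LossWeights(lambda1=0.0, lambda2=0.0)
    assert autoencoder_total(S2, S, p, p.f0, p.formant_freq[:, :4], w) == \
        pytest.approx(mss_loss(S2, S))


def test_autoencoder_total_monotone_in_supervision_error():
    S, p = _pair()
    worse = flat_params(40)
    worse.f0 = worse.f0 + 50.0
    a = autoencoder_total(S, S, p, p.f0, p.formant_freq[:, :4])
    b = autoencoder_total(S, S, worse, p.f0, p.formant_freq[:, :4])
    assert b > a


def test_decoder_total_reduces_to_autoencoder_when_guidance_matches():
    S, p = _pair()
    ae = autoencoder_total(S, S, p, p.f0, p.formant_freq[:, :4])
    dec = decoder_total(S, S, p, p.f0, p.formant_freq[:, :4], guidance=p)
    assert dec == pytest.approx(ae)
    w0 = LossWeights(lambda3=0.0)
    other = flat_params(40, alpha=0.1)
    assert decoder_total(S, S, p, p.f0, p.formant_freq[:, :4], other, w0) == \
        pytest.approx(autoencoder_total(S, S, p, p.f0, p.formant_freq[:, :4]))


def test_decoder_total_hand_computed_single_frame_reference_term():
    # 40 frames for STOI validity; reference error only on loudness
    S, p = _pair()
    q = flat_params(40)
    q.loudness = q.loudness + 0.5
    dec = decoder_total(S, S, q, q.f0, q.formant_freq[:, :4], guidance=p)
    ae = autoencoder_total(S, S, q, q.f0, q.formant_freq[:, :4])
    assert dec - ae == pytest.approx(1.5 * 0.25, rel=1e-9)


# -- differentiability -------------------------------------------------------

def test_losses_differentiable_wrt_prediction():
    T, K = 35, 256
    target = RNG.random((T, K)) + 0.05
    x0 = RNG.random((T, K)) + 0.05
    t = Tensor(x0, requires_grad=True)
    total = mss_loss(t, Tensor(target)) + 1.2 * (-stoi_plus(t, Tensor(target)))
    total.backward()
    auto = t.grad
    rng_idx = np.random.default_rng(0)
    picks = [(int(a), int(b)) for a, b in
             zip(rng_idx.integers(0, T, 6), rng_idx.integers(0, K, 6))]
    for (i, j) in picks:
        eps = 1e-6
        xp, xm = x0.copy(), x0.copy()
        xp[i, j] += eps
        xm[i, j] -= eps
        fp = mss_loss(Spectrogram(xp), Spectrogram(target)) - 1.2 * stoi_plus(
            Spectrogram(xp), Spectrogram(target))
        fm = mss_loss(Spectrogram(xm), Spectrogram(target)) - 1.2 * stoi_plus(
            Spectrogram(xm), Spectrogram(target))
        num = (fp - fm) / (2 * eps)
        assert auto[i, j] == pytest.approx(num, rel=1e-3, abs=1e-6)
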