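"""Occlusion-analysis tests on data with a known generative mapping."""

from dataclasses import replace

import numpy as np
import pytest

from neurovox.decoders import DecoderConfig, DecoderTrainConfig, train_decoder
from neurovox.occlusion import (contribution_map, derangement,
                                electrode_contribution, noise_floor_map,
                                spectrogram_pcc)
from neurovox.types import Spectrogram


def test_pcc_trivial_cases():
    rng = np.random.default_rng(0)
    S = Spectrogram(rng.random((10, 16)))
    assert spectrogram_pcc(S, S) == pytest.approx(1.0)
    neg = Spectrogram(-np.asarray(S.values) + 2.0)
    assert spectrogram_pcc(neg, S) == pytest.approx(-1.0)


def test_pcc_hand_computed_two_by_two():
    a = np.array([[1.0, 2.0], [3.0, 4.0]])
    b = np.array([[2.0, 2.5], [4.0, 3.0]])
    av, bv = a.ravel() - a.mean(), b.ravel() - b.mean()
    expected = (av @ bv) / np.sqrt((av @ av) * (bv @ bv))
    assert spectrogram_pcc(Spectrogram(a), Spectrogram(b)) == \
        pytest.approx(expected)


def test_pcc_zero_variance_rejected():
    with pytest.raises(ValueError):
        spectrogram_pcc(Spectrogram(np.ones((4, 4))),
                        Spectrogram(np.random.default_rng(0).random((4, 4))))


def test_derangement_has_no_fixed_points():
    rng = np.random.default_rng(0)
    for n in (2, 5, 20):
        perm = derangement(n, rng)
        assert not np.any(perm == np.arange(n))
        assert sorted(perm) == list(range(n))
    with pytest.raises(ValueError):
        derangement(1, rng)


@pytest.fixture(scope="module")
def trained_tiny(tiny_dataset):
    cfg = replace(DecoderConfig().toy(), backbone="lstm", causal=True,
                  channels=16)
    dec, _ = train_decoder(tiny_dataset.train, tiny_dataset.speaker, cfg,
                           DecoderTrainConfig(steps=80, batch_size=4,
                                              lr=2e-3), seed=7)
    return dec, cfg


def test_contribution_map_shape_and_reproducibility(tiny_dataset, trained_tiny):
    dec, _ = trained_tiny
    cm = contribution_map(dec, tiny_dataset.speaker, tiny_dataset.test, seed=1)
    assert cm.contrib.shape == tiny_dataset.test[0]["ecog"].grid_shape
    assert np.isfinite(cm.contrib).all()
    cm2 = contribution_map(dec, tiny_dataset.speaker, tiny_dataset.test, seed=1)
    np.testing.assert_array_equal(cm.contrib, cm2.contrib)


def test_zero_variance_electrode_contributes_exactly_zero(tiny_dataset,
                                                          trained_tiny):
    dec, _ = trained_tiny
    test = []
    for tr in tiny_dataset.test:
        tr = dict(tr)
        ecog = tr["ecog"]
        vals = ecog.values.copy()
        vals[:, 0, 0] = 0.0          # dead electrode
        from neurovox.types import ECoGTensor
        tr["ecog"] = ECoGTensor(vals, valid_mask=ecog.valid_mask)
        test.append(tr)
    cm = contribution_map(dec, tiny_dataset.speaker, test, seed=0)
    assert cm.contrib[0, 0] == 0.0


def test_electrode_contribution_bounds_and_errors(tiny_dataset, trained_tiny):
    dec, _ = trained_tiny
    val = electrode_contribution(dec, tiny_dataset.speaker,
                                 tiny_dataset.test, (0, 1), seed=0)
    assert np.isfinite(val)
    with pytest.raises(ValueError):
        electrode_contribution(dec, tiny_dataset.speaker, tiny_dataset.test,
                               (9, 9))
    with pytest.raises(ValueError):
        electrode_contribution(dec, tiny_dataset.speaker, [], (0, 0))


def test_informative_electrodes_score_above_noise_floor(tiny_dataset,
                                                        trained_tiny):
    dec, cfg = trained_tiny
    cm = contribution_map(dec, tiny_dataset.speaker, tiny_dataset.test, seed=1)
    floor = noise_floor_map(tiny_dataset.train, tiny_dataset.test,
                            tiny_dataset.speaker, cfg,
                            DecoderTrainConfig(steps=80, batch_size=4,
                                               lr=2e-3), seed=3)
    strength = tiny_dataset.mapping.electrode_strength().reshape(
        tiny_dataset.test[0]["ecog"].grid_shape)
    informative = strength > 0
    # the strongest informative electrode clears the matched noise floor
    gap = cm.contrib[informative] - floor.contrib[informative]
    assert gap.max() > 0
    cm.noise_floor = floor.contrib
    sig = cm.significant()
    assert sig.shape == cm.contrib.shape
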