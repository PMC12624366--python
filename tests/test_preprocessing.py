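"""Preprocessing transforms: reference, filter, resample, baseline, smoothing."""

import numpy as np
import pandas as pd
import pytest

import touchdecode as td
from touchdecode.preprocessing import (
    PreprocessingConfig, bandpass_filter, baseline_correct,
    common_average_reference, downsample, moving_average, preprocess,
)


def _epochs(data, fs=100.0, t0=-0.1):
    data = np.asarray(data, float)
    n_tr, n_ch, n_s = data.shape
    time = t0 + np.arange(n_s) / fs
    trials = pd.DataFrame(
        {
            "stimulus_id": [f"s{i}" for i in range(n_tr)],
            "sequence_index": np.zeros(n_tr, int),
            "is_target": [False] * n_tr,
        }
    )
    return td.EpochArray(data, fs, time, [f"c{i}" for i in range(n_ch)], trials)


class TestCommonAverageReference:
    def test_channel_mean_is_zero(self, toy_epochs):
        out = common_average_reference(toy_epochs)
        np.testing.assert_allclose(out.data.mean(axis=1), 0, atol=1e-10)

    def test_antisymmetric_pair_unchanged(self):
        v = np.random.default_rng(0).standard_normal((2, 1, 20))
        ep = _epochs(np.concatenate([v, -v], axis=1))
        out = common_average_reference(ep)
        np.testing.assert_allclose(out.data, ep.data, atol=1e-12)

    def test_constant_channels_recentered(self):
        ep = _epochs(np.stack([np.ones((2, 10)), 3 * np.ones((2, 10))], axis=1))
        out = common_average_reference(ep)
        np.testing.assert_allclose(out.data[:, 0], -1.0)
        np.testing.assert_allclose(out.data[:, 1], 1.0)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(_epochs(np.ones((1, 1, 10))))


class TestBandpass:
    def test_dc_strongly_attenuated_on_long_segment(self):
        fs = 512.0
        ep = _epochs(5.0 * np.ones((1, 2, int(60 * fs))), fs=fs, t0=0.0)
        out = bandpass_filter(ep, 0.1, 100.0)
        assert np.abs(out.data).mean() < 0.1 * 5.0

    def test_passband_sinusoid_preserved(self):
        fs = 512.0
        t = np.arange(int(30 * fs)) / fs
        ep = _epochs(np.sin(2 * np.pi * 10 * t)[None, None, :], fs=fs, t0=0.0)
        out = bandpass_filter(ep, 0.1, 100.0)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert out.data[0, 0, mid].max() == pytest.approx(1.0, rel=0.05)

    def test_linearity(self, toy_epochs):
        big = toy_epochs.copy(data=toy_epochs.data * 3.5)
        np.testing.assert_allclose(
            bandpass_filter(big, 0.5, 40.0).data,
            3.5 * bandpass_filter(toy_epochs, 0.5, 40.0).data,
            atol=1e-10,
        )

    def test_corner_at_nyquist_rejected(self, toy_epochs):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(toy_epochs, 0.1, 50.0)  # fs = 100 Hz


class TestDownsample:
    def test_standard_window_sample_counts(self):
        fs = 2048.0
        n = int(round(0.9 * fs))
        assert n == 1843
        ep = _epochs(np.zeros((1, 2, n)), fs=fs)
        out = downsample(ep, 200.0)
        assert out.n_samples == 180
        assert out.sampling_rate == 200.0

    def test_constant_preserved(self):
        ep = _epochs(4.2 * np.ones((1, 2, 461)), fs=512.0)
        out = downsample(ep, 200.0)
        np.testing.assert_allclose(out.data, 4.2, rtol=1e-4)

    def test_below_nyquist_sinusoid_preserved(self):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        ep = _epochs(np.sin(2 * np.pi * 10 * t)[None, None, :], fs=fs, t0=0.0)
        out = downsample(ep, 200.0)
        mid = slice(out.n_samples // 4, 3 * out.n_samples // 4)
        assert np.abs(out.data[0, 0, mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_upsampling_rejected(self, toy_epochs):
        with pytest.raises(ValueError):
            downsample(toy_epochs, 500.0)


class TestBaseline:
    def test_constant_trace_zeroed(self):
        ep = _epochs(7.0 * np.ones((2, 2, 90)))
        out = baseline_correct(ep, (-0.1, 0.0))
        np.testing.assert_allclose(out.data, 0.0)

    def test_explicit_example(self):
        ep = _epochs(np.array([[[1.0, 1.0, 3.0, 5.0]]]), fs=20.0, t0=-0.1)
        out = baseline_correct(ep, (-0.1, 0.0))
        np.testing.assert_allclose(out.data[0, 0], [0.0, 0.0, 2.0, 4.0])

    def test_window_mean_is_zero_after_correction(self, toy_epochs):
        out = baseline_correct(toy_epochs, (-0.1, 0.0))
        mask = (out.time >= -0.1) & (out.time < 0.0)
        np.testing.assert_allclose(
            out.data[..., mask].mean(axis=-1), 0.0, atol=1e-12
        )

    def test_empty_window_rejected(self, toy_epochs):
        with pytest.raises(ValueError):
            baseline_correct(toy_epochs, (5.0, 6.0))


class TestMovingAverage:
    def test_constant_unchanged(self):
        ep = _epochs(2.5 * np.ones((1, 1, 50)))
        np.testing.assert_allclose(moving_average(ep, 10).data, 2.5)

    def test_impulse_spreads_to_uniform_plateau(self):
        data = np.zeros((1, 1, 50))
        data[0, 0, 25] = 1.0
        out = moving_average(_epochs(data), 10)
        covered = out.data[0, 0][out.data[0, 0] > 0]
        assert len(covered) == 10
        np.testing.assert_allclose(covered, 0.1)

    def test_linear_ramp_unchanged_in_interior(self):
        ramp = np.arange(60.0)[None, None, :]
        out = moving_average(_epochs(ramp), 9)  # odd window: exact symmetry
        np.testing.assert_allclose(out.data[0, 0, 10:-10], ramp[0, 0, 10:-10])

    def test_window_longer_than_epoch_rejected(self, toy_epochs):
        with pytest.raises(ValueError):
            moving_average(toy_epochs, 1000)


class TestComposedChain:
    def test_zero_in_zero_out(self):
        ep = _epochs(np.zeros((2, 3, 461)), fs=512.0)
        out = preprocess(ep)
        assert not out.data.any()
        assert out.sampling_rate == 200.0
        assert out.n_samples == 180

    def test_all_steps_disabled_is_identity(self, toy_epochs):
        cfg = PreprocessingConfig(
            car=False, hp_hz=None, lp_hz=None, resample_hz=None,
            baseline=None, smooth_samples=None,
        )
        out = preprocess(toy_epochs, cfg)
        np.testing.assert_array_equal(out.data, toy_epochs.data)

    def test_chain_commutes_with_channel_permutation(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((4, 6, 461))
        ep = _epochs(data, fs=512.0)
        perm = rng.permutation(6)
        ep_perm = ep.copy(
            data=data[:, perm], channel_names=[ep.channel_names[i] for i in perm]
        )
        np.testing.assert_allclose(
            preprocess(ep).data[:, perm], preprocess(ep_perm).data, atol=1e-10
        )

    def test_unknown_config_key_rejected(self, toy_epochs):
        with pytest.raises(ValueError, match="unknown preprocessing"):
            preprocess(toy_epochs, {"lowpass": 40.0})
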