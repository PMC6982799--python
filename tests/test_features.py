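"""Mel filterbank, MFCC/CMN, deltas and LPC front-ends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apiscan.audio_io import AudioClip
from apiscan.features import (FeatureSequence, LpcConfig, add_deltas,
                              build_mel_filterbank, cepstral_mean_normalize,
                              hz_to_mel, levinson_durbin, lpc, lpc_to_cepstra,
                              load_features, mfcc, save_features,
                              toeplitz_lpc_oracle)


class TestMelFilterbank:
    def test_mel_scale_reference_point(self):
        assert hz_to_mel(700.0) == pytest.approx(2595 * np.log10(2), abs=1e-9)

    def test_eight_filter_bank_shape_and_peaks(self):
        bank = build_mel_filterbank(n_filters=8)
        assert bank.n_filters == 8
        assert bank.weights.shape == (8, 257)
        assert np.all(bank.weights >= 0)
        assert np.allclose(bank.weights.max(axis=1), 1.0)

    def test_centers_equally_spaced_in_mel(self):
        bank = build_mel_filterbank(n_filters=26)
        centers_hz = np.array([np.argmax(w) for w in bank.weights]) * 16_000 / 512
        mels = np.asarray(hz_to_mel(centers_hz))
        spacing = np.diff(mels)
        # equal up to bin-quantization error
        assert spacing.std() / spacing.mean() < 0.12

    def test_full_band_coverage_between_first_and_last_center(self):
        bank = build_mel_filterbank(n_filters=26)
        total = bank.weights.sum(axis=0)
        first = int(np.argmax(bank.weights[0]))
        last = int(np.argmax(bank.weights[-1]))
        assert np.all(total[first:last + 1] > 0)

    def test_too_many_filters_for_resolution_rejected(self):
        with pytest.raises(ValueError, match="filter"):
            build_mel_filterbank(n_filters=40, f_low=0, f_high=300.0)


class TestMfcc:
    def test_dimensions_13_statics_39_total(self, swarm_clip):
        feats = mfcc(swarm_clip)
        assert feats.static_dim == 13
        assert feats.data.shape == (298, 39)

    def test_deterministic(self, swarm_clip):
        a = mfcc(swarm_clip).data
        b = mfcc(swarm_clip).data
        assert np.array_equal(a, b)

    def test_gain_change_shifts_only_energy_like_terms(self, tone_clip):
        base = mfcc(tone_clip, with_deltas=False).data
        quieter = AudioClip(tone_clip.samples * 0.5, 16_000)
        scaled = mfcc(quieter, with_deltas=False).data
        # cepstra c1..c12 invariant; energy shifts by log(0.25) in power
        assert np.allclose(scaled[:, :12], base[:, :12], atol=1e-8)
        assert np.allclose(scaled[:, 12] - base[:, 12], np.log(0.25), atol=1e-8)

    def test_all_zero_frames_finite(self):
        clip = AudioClip(np.zeros(48_000) + 1e-30, 16_000)
        clip.samples[:] = 0.0
        feats = mfcc(clip)
        assert np.all(np.isfinite(feats.data))

    def test_roundtrip_container_and_kind(self, tmp_path, swarm_clip):
        feats = mfcc(swarm_clip)
        p = tmp_path / "f.apfs"
        save_features(p, feats)
        back = load_features(p)
        assert back.kind == "MFCC"
        assert back.data.shape == feats.data.shape
        assert np.allclose(back.data, feats.data, atol=1e-4)


class TestDeltas:
    def test_constant_sequence_zero_deltas(self):
        statics = FeatureSequence(np.ones((20, 13)) * 3.0, "MFCC")
        out = add_deltas(statics)
        assert out.data.shape == (20, 39)
        assert np.allclose(out.data[:, 13:], 0.0)

    def test_linear_ramp_unit_delta_zero_accel(self):
        t = np.arange(30, dtype=float)
        statics = FeatureSequence(np.tile(t[:, None], (1, 13)), "MFCC")
        out = add_deltas(statics)
        d1 = out.data[:, 13:26]
        d2 = out.data[:, 26:]
        assert np.allclose(d1[4:-4], 1.0)
        assert np.allclose(d2[4:-4], 0.0, atol=1e-12)

    def test_matches_bruteforce_regression(self, rng):
        x = rng.standard_normal((40, 13))
        out = add_deltas(FeatureSequence(x.copy(), "MFCC"), window_w=2)
        # brute-force per frame with replicated edges
        padded = np.vstack([x[0], x[0], x, x[-1], x[-1]])
        denom = 2 * (1 + 4)
        for t in range(40):
            d = (1 * (padded[t + 3] - padded[t + 1])
                 + 2 * (padded[t + 4] - padded[t])) / denom
            assert np.allclose(out.data[t, 13:26], d, atol=1e-12)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            add_deltas(FeatureSequence(np.ones((3, 13)), "MFCC"))


class TestCmn:
    def test_column_means_zero(self, swarm_clip):
        feats = cepstral_mean_normalize(mfcc(swarm_clip))
        assert feats.kind == "MFCC_CMN"
        assert np.max(np.abs(feats.statics.mean(axis=0))) < 1e-9

    def test_idempotent_on_zero_mean_input(self, swarm_clip):
        once = cepstral_mean_normalize(mfcc(swarm_clip))
        # statics already zero-mean: renormalizing must not move them
        again_statics = once.statics - once.statics.mean(axis=0)
        assert np.allclose(again_statics, once.statics, atol=1e-12)

    def test_shift_invariance(self, swarm_clip):
        feats = mfcc(swarm_clip)
        shifted = FeatureSequence(feats.data.copy(), "MFCC",
                                  static_dim=feats.static_dim)
        shifted.data[:, 0] += 5.0
        a = cepstral_mean_normalize(feats)
        b = cepstral_mean_normalize(shifted)
        assert np.allclose(a.data, b.data, atol=1e-9)


class TestLpc:
    def test_white_autocorrelation_gives_zero_coefficients(self):
        r = np.zeros(13)
        r[0] = 1.0
        a, E, k = levinson_durbin(r, 12)
        assert np.allclose(a, 0.0)
        assert E == pytest.approx(1.0)

    def test_order_one_closed_form(self):
        a, E, _ = levinson_durbin(np.array([1.0, 0.5]), 1)
        assert a[0] == pytest.approx(0.5)
        assert E == pytest.approx(0.75)

    def test_silent_frame_floored(self):
        a, E, _ = levinson_durbin(np.zeros(13), 12)
        assert np.allclose(a, 0.0)
        assert E > 0

    @pytest.mark.parametrize("order", [2, 4, 8])
    def test_matches_dense_toeplitz_solve(self, rng, order):
        # autocorrelation of a random stable AR process realization
        from scipy.signal import lfilter
        poles = rng.uniform(-0.6, 0.6, order)
        ar = np.poly(poles)
        x = lfilter([1.0], ar, rng.standard_normal(2000))
        full = np.correlate(x, x, mode="full")
        r = full[len(x) - 1 : len(x) + order]
        a, _, _ = levinson_durbin(r, order)
        assert np.allclose(a, toeplitz_lpc_oracle(r, order), atol=1e-8)

    def test_reflection_coefficients_bounded_error_monotone(self, rng):
        x = rng.standard_normal(1000)
        full = np.correlate(x, x, mode="full")
        r = full[999 : 999 + 13]
        _, _, ks = levinson_durbin(r, 12)
        assert np.all(np.abs(ks) <= 1.0 + 1e-12)
        # E_i = r0 * prod(1 - k^2) is non-increasing term by term
        errs = r[0] * np.cumprod(1 - ks ** 2)
        assert np.all(np.diff(errs) <= 1e-12)

    def test_feature_layout_matches_mfcc(self, swarm_clip):
        feats = lpc(swarm_clip)
        assert feats.kind == "LPC"
        assert feats.data.shape == (298, 39)
        assert np.all(np.isfinite(feats.data))

    def test_cepstra_recursion_first_terms(self):
        # for a single-pole predictor a1, cepstra are a1, a1^2/2, a1^3/3, ...
        a = np.array([0.5])
        c = lpc_to_cepstra(a, 4)
        assert np.allclose(c, [0.5, 0.125, 0.5 ** 3 / 3, 0.5 ** 4 / 4])

    def test_coefficients_representation_selectable(self, tone_clip):
        feats = lpc(tone_clip, LpcConfig(order=12,
                                         representation="coefficients"))
        assert feats.data.shape[1] == 39

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_levinson_matches_toeplitz_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(400)
        full = np.correlate(x, x, mode="full")
        r = full[399 : 399 + 13]
        a, _, _ = levinson_durbin(r, 12)
        assert np.allclose(a, toeplitz_lpc_oracle(r, 12), atol=1e-8)
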