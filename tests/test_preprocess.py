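import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpwave.preprocess import (
    DegenerateSignalWarning,
    FrameSet,
    PreprocessConfig,
    SpectralPreprocessor,
    build_labels,
    build_model_input,
    frame_signal,
    invert_labels,
    randomize_amplitude,
    spectral_transform,
    zscore,
)


def naive_dft(x):
    """Independent O(N^2) DFT-sum oracle."""
    n = len(x)
    k = np.arange(n)
    kernel = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return kernel @ x


class TestFraming:
    @pytest.mark.parametrize("n,window,expected", [
        (203_000, 250, 812),
        (175_000, 250, 700),
        (28_000, 250, 112),
        (500, 250, 2),
        (249, 250, 0),
    ])
    def test_frame_counts(self, n, window, expected):
        signal = np.arange(n, dtype=float)
        if expected == 0:
            with pytest.warns(DegenerateSignalWarning):
                fs = frame_signal(signal, window)
        else:
            fs = frame_signal(signal, window)
        assert fs.n_frames == expected

    def test_frames_conserve_prefix(self, rng):
        signal = rng.normal(size=1234)
        fs = frame_signal(signal, 100)
        np.testing.assert_array_equal(fs.frames.ravel(), signal[:1200])
        np.testing.assert_array_equal(fs.offsets, np.arange(12) * 100)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError, match="window_len"):
            frame_signal(np.zeros(100), 1)


class TestAmplitudeRandomization:
    def test_scaling_definition(self, random_frames):
        cfg = PreprocessConfig(amp_low=0.5, amp_high=0.5 + 1e-12)

        class Stub:
            def uniform(self, lo, hi, size):
                return np.full(size, 0.5)

        scaled, factors = randomize_amplitude(random_frames, Stub(), cfg)
        np.testing.assert_allclose(scaled.frames, random_frames.frames * 0.5)
        np.testing.assert_allclose(factors, 0.5)

    def test_same_seed_same_factors(self, random_frames):
        cfg = PreprocessConfig()
        _, f1 = randomize_amplitude(random_frames, np.random.default_rng(5), cfg)
        _, f2 = randomize_amplitude(random_frames, np.random.default_rng(5), cfg)
        np.testing.assert_array_equal(f1, f2)

    def test_factor_distribution_moments(self):
        """Uniform-distribution moments: mean within 3 standard errors."""
        cfg = PreprocessConfig(amp_low=1e-6, amp_high=1.0)
        frames = FrameSet(np.ones((10_000, 2)), 125.0, np.arange(10_000) * 2)
        _, factors = randomize_amplitude(frames, np.random.default_rng(0), cfg)
        assert factors.min() >= cfg.amp_low and factors.max() <= cfg.amp_high
        expected_mean = (cfg.amp_low + cfg.amp_high) / 2
        se = (cfg.amp_high - cfg.amp_low) / np.sqrt(12 * len(factors))
        assert abs(factors.mean() - expected_mean) < 3 * se


class TestSpectralTransform:
    def test_constant_frame(self):
        mag, phase = spectral_transform(np.full(250, 3.0))
        assert mag[0] == pytest.approx(250 * 3.0, abs=1e-9)
        np.testing.assert_allclose(mag[1:], 0.0, atol=1e-9)
        assert phase[0] == pytest.approx(0.0)

    def test_pure_cosine_bins(self):
        n = 250
        frame = np.cos(2 * np.pi * 5 * np.arange(n) / n)
        mag, _ = spectral_transform(frame)
        assert mag[5] == pytest.approx(125.0, abs=1e-6)
        assert mag[245] == pytest.approx(125.0, abs=1e-6)
        others = np.delete(mag, [5, 245])
        np.testing.assert_allclose(others, 0.0, atol=1e-6)

    def test_matches_naive_dft_oracle(self, rng):
        worst = 0.0
        for _ in range(100):
            frame = rng.normal(size=250)
            mag, phase = spectral_transform(frame)
            ref = naive_dft(frame)
            scale = np.abs(ref).max()
            worst = max(worst, np.max(np.abs(mag - np.abs(ref))) / scale)
            strong = np.abs(ref) > 1e-6 * scale
            worst = max(worst, np.max(np.abs(
                np.angle(np.exp(1j * (phase[strong] - np.angle(ref[strong])))))))
        assert worst < 1e-6

    def test_positive_scaling_behaviour(self, rng):
        frame = rng.normal(size=250)
        mag, phase = spectral_transform(frame)
        for c in (1e-4, 0.5, 7.0):
            mag_c, phase_c = spectral_transform(c * frame)
            np.testing.assert_allclose(mag_c, c * mag, rtol=1e-9, atol=1e-12)
            strong = mag > 1e-9
            np.testing.assert_allclose(phase_c[strong], phase[strong], atol=1e-9)

    def test_parseval_energy(self, rng):
        frame = rng.normal(size=250)
        mag, _ = spectral_transform(frame)
        lhs = np.sum(mag**2)
        rhs = 250 * np.sum(frame**2)
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_onesided_option(self, rng):
        cfg = PreprocessConfig(spectrum="onesided")
        mag, phase = spectral_transform(rng.normal(size=250), cfg)
        assert mag.shape == (126,) and phase.shape == (126,)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            spectral_transform(np.array([1.0, np.inf, 0.0]))


class TestZScore:
    def test_closed_form(self):
        np.testing.assert_allclose(
            zscore(np.array([1.0, 2.0, 3.0])),
            [-1.224745, 0.0, 1.224745], atol=1e-5)

    def test_constant_vector_degenerates_to_zero(self):
        with pytest.warns(DegenerateSignalWarning):
            out = zscore(np.full(10, 4.2))
        np.testing.assert_array_equal(out, 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.array([1.0]))

    @settings(deadline=None, max_examples=30)
    @given(
        c=st.floats(0.01, 100),
        d=st.floats(-100, 100),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance(self, c, d, seed):
        x = np.random.default_rng(seed).normal(size=64)
        np.testing.assert_allclose(zscore(c * x + d), zscore(x), atol=1e-8)

    def test_output_moments(self, rng):
        out = zscore(rng.normal(size=500))
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1) < 1e-6


class TestBuildModelInput:
    def test_shape_and_channel_moments(self, random_frames, rng):
        cfg = PreprocessConfig()
        out = build_model_input(random_frames, random_frames,
                                np.random.default_rng(1), cfg)
        assert out.data.shape == (100, 4, 250)
        np.testing.assert_allclose(out.data.mean(axis=-1), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.data.std(axis=-1), 1.0, atol=1e-6)

    def test_scale_invariance(self, rng):
        """Per-frame positive rescaling of the raw signals leaves the
        spectral input unchanged (the central invariance, exact by
        design: magnitude scale is removed by the z-score, phase does
        not depend on scale at all)."""
        frames = rng.normal(size=(100, 250))
        offsets = np.arange(100, dtype=np.int64) * 250
        ecg = FrameSet(frames, 125.0, offsets)
        ppg = FrameSet(frames[::-1].copy(), 125.0, offsets)
        cfg = PreprocessConfig()
        base = build_model_input(ppg, ecg, np.random.default_rng(9), cfg).data
        for trial in range(20):
            scales = rng.uniform(1e-3, 1e3, size=100)
            ecg_s = FrameSet(frames * scales[:, None], 125.0, offsets)
            ppg_s = FrameSet(frames[::-1] * scales[::-1, None], 125.0, offsets)
            out = build_model_input(ppg_s, ecg_s, np.random.default_rng(9), cfg).data
            np.testing.assert_allclose(out, base, atol=1e-6)

    def test_frame_count_mismatch_rejected(self, random_frames):
        short = FrameSet(random_frames.frames[:10], 125.0,
                         random_frames.offsets[:10])
        with pytest.raises(ValueError, match="mismatch"):
            build_model_input(random_frames, short, np.random.default_rng(0),
                              PreprocessConfig())


class TestLabels:
    def test_round_trip_to_mmhg(self, rng):
        frames = FrameSet(rng.uniform(40, 180, size=(20, 250)), 125.0,
                          np.arange(20) * 250)
        labels = build_labels(frames)
        back = invert_labels(labels.labels, (labels.abp_mean, labels.abp_std))
        np.testing.assert_allclose(back, frames.frames, atol=1e-6)

    def test_identity_stats(self, rng):
        frames = FrameSet(rng.normal(size=(5, 250)), 125.0, np.arange(5) * 250)
        labels = build_labels(frames, stats=(0.0, 1.0))
        np.testing.assert_array_equal(labels.labels, frames.frames)

    def test_self_computed_stats_are_global(self, rng):
        frames = FrameSet(rng.uniform(40, 180, size=(20, 250)), 125.0,
                          np.arange(20) * 250)
        labels = build_labels(frames)
        assert abs(labels.labels.mean()) < 1e-9
        assert abs(labels.labels.std() - 1) < 1e-9

    def test_invert_anchors(self):
        assert invert_labels(np.array(0.0), (90.0, 15.0)) == pytest.approx(90.0)
        assert invert_labels(np.array(1.0), (90.0, 15.0)) == pytest.approx(105.0)

    def test_degenerate_abp_rejected(self):
        frames = FrameSet(np.full((3, 250), 100.0), 125.0, np.arange(3) * 250)
        with pytest.raises(ValueError, match="degenerate"):
            build_labels(frames)


class TestSpectralPreprocessor:
    def test_sklearn_contract(self, rng):
        from sklearn.base import clone

        prep = SpectralPreprocessor(seed=3)
        assert clone(prep).get_params() == prep.get_params()
        raw = rng.normal(size=(8, 2, 250))
        out = prep.fit_transform(raw)
        assert out.shape == (8, 4, 250)
        np.testing.assert_array_equal(out, prep.transform(raw))

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            SpectralPreprocessor().transform(np.zeros((4, 3, 250)))
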