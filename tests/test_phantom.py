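"""Phantom generation, noise corruption, and N-frame averaging."""

from __future__ import annotations

import numpy as np
import pytest

import octenhance as oe
from octenhance.errors import ConfigError
from octenhance.metrics import default_windows, window_snr


def brute_force_render(truth: oe.PhantomTruth) -> np.ndarray:
    """Per-pixel re-rendering of a vessel-free phantom from its returned
    geometry; independent of the vectorized implementation."""
    cfg = truth.config
    sig = lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))  # noqa: E731
    out = np.zeros((cfg.height, cfg.width))
    b = truth.boundaries
    refl = truth.layer_reflectivities
    for r in range(cfg.height):
        for c in range(cfg.width):
            v = cfg.background
            for k in range(len(refl)):
                band = sig((r - b[k, c]) / cfg.edge_softness) - sig(
                    (r - b[k + 1, c]) / cfg.edge_softness
                )
                v += (refl[k] - cfg.background) * band
            depth = r - b[-1, c]
            v += (
                (cfg.choroid_reflectivity - cfg.background)
                * sig(depth / cfg.edge_softness)
                * np.exp(-truth.attenuation_rate * max(depth, 0.0))
            )
            out[r, c] = min(max(v, 0.0), 1.0)
    return out


class TestGenerateCleanBscan:
    def test_deterministic_for_fixed_seed(self):
        cfg = oe.PhantomConfig(n_layers=5)
        a = oe.generate_clean_bscan(cfg, seed=7)
        b = oe.generate_clean_bscan(cfg, seed=7)
        np.testing.assert_array_equal(a.clean.pixels, b.clean.pixels)
        np.testing.assert_array_equal(a.boundaries, b.boundaries)

    def test_seed_sensitivity(self):
        cfg = oe.PhantomConfig()
        a = oe.generate_clean_bscan(cfg, seed=7)
        b = oe.generate_clean_bscan(cfg, seed=8)
        assert np.any(a.clean.pixels != b.clean.pixels)

    def test_vessel_free_image_matches_band_render_oracle(self):
        cfg = oe.PhantomConfig(height=32, width=32, n_vessels=0)
        truth = oe.generate_clean_bscan(cfg, seed=3)
        oracle = brute_force_render(truth)
        np.testing.assert_allclose(truth.clean.pixels, oracle, atol=1e-12)

    def test_invariants(self, small_truth):
        img = small_truth.clean
        assert np.all(np.isfinite(img.pixels))
        assert img.pixels.min() >= 0 and img.pixels.max() <= 1
        assert np.all(np.diff(small_truth.boundaries, axis=0) >= 0)
        assert len(small_truth.layer_reflectivities) == small_truth.config.n_layers

    @pytest.mark.parametrize(
        "kwargs", [{"height": 0}, {"width": -3}, {"n_layers": 1}, {"n_vessels": -1}]
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ConfigError):
            oe.PhantomConfig(**kwargs)


class TestAddNoise:
    def test_zero_sigma_is_identity(self, small_truth):
        out = oe.add_noise(small_truth.clean, oe.NoiseSpec(model="gaussian", sigma=0.0), 1)
        np.testing.assert_array_equal(out.pixels, small_truth.clean.pixels)

    def test_gaussian_sample_std(self):
        img = oe.BScan(np.full((256, 256), 0.5))
        spec = oe.NoiseSpec(model="gaussian", sigma=0.05)
        stds = []
        for seed in range(10):
            out = oe.add_noise(img, spec, seed)
            stds.append((out.pixels - img.pixels).std())
        assert np.mean(stds) == pytest.approx(0.05, rel=0.02)

    def test_rayleigh_mean_uncentered(self):
        img = oe.BScan(np.zeros((256, 256)))
        spec = oe.NoiseSpec(model="rayleigh", sigma=0.2)
        means = [oe.add_noise(img, spec, s).pixels.mean() for s in range(10)]
        assert np.mean(means) == pytest.approx(0.2 * np.sqrt(np.pi / 2), rel=0.02)

    def test_default_sigmas(self):
        assert oe.NoiseSpec(model="gaussian").effective_sigma == 0.5
        assert oe.NoiseSpec(model="rayleigh").effective_sigma == 0.2

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigError):
            oe.NoiseSpec(model="poisson")

    def test_deterministic_per_seed(self, small_truth):
        spec = oe.NoiseSpec(sigma=0.1)
        a = oe.add_noise(small_truth.clean, spec, 5)
        b = oe.add_noise(small_truth.clean, spec, 5)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestSimulateAveragedScan:
    def test_single_frame_average_equals_noisy(self, small_truth):
        spec = oe.NoiseSpec(sigma=0.1, correlation=0.0, jitter_px=0)
        s = oe.simulate_averaged_scan(small_truth, 1, spec, 2)
        np.testing.assert_array_equal(s.averaged.pixels, s.noisy.pixels)

    def test_sqrt_n_residual_noise(self, small_truth):
        spec = oe.NoiseSpec(sigma=0.1)
        stds = []
        for seed in range(10):
            s = oe.simulate_averaged_scan(small_truth, 9, spec, seed)
            stds.append((s.averaged.pixels - s.clean.pixels).std())
        assert np.mean(stds) == pytest.approx(0.1 / 3, rel=0.15)

    def test_jitter_blurs_the_average(self, small_truth):
        base = oe.NoiseSpec(sigma=0.05)
        jit = oe.NoiseSpec(sigma=0.05, jitter_px=2)
        s_plain, s_jit = [], []
        for seed in range(10):
            s_plain.append(oe.ssim(
                oe.simulate_averaged_scan(small_truth, 9, base, seed).averaged,
                small_truth.clean))
            s_jit.append(oe.ssim(
                oe.simulate_averaged_scan(small_truth, 9, jit, seed).averaged,
                small_truth.clean))
        assert np.mean(s_jit) < np.mean(s_plain)

    def test_invalid_frame_count(self, small_truth):
        with pytest.raises(ConfigError):
            oe.simulate_averaged_scan(small_truth, 0, oe.NoiseSpec(sigma=0.1), 1)

    @pytest.mark.parametrize("n_frames", [4, 9, 16])
    def test_window_snr_follows_sqrt_n(self, n_frames):
        cfg = oe.PhantomConfig()
        spec = oe.NoiseSpec(sigma=0.1)
        ratios = []
        for seed in range(10):
            truth = oe.generate_clean_bscan(cfg, 300 + seed)
            s = oe.simulate_averaged_scan(truth, n_frames, spec, 400 + seed)
            w = default_windows(truth.clean)
            ratios.append(window_snr(s.averaged, w) / window_snr(s.noisy, w))
        assert np.mean(ratios) == pytest.approx(np.sqrt(n_frames), rel=0.15)

    def test_correlated_noise_caps_the_gain(self):
        cfg = oe.PhantomConfig()
        spec = oe.NoiseSpec(sigma=0.1, correlation=0.5)
        ratios = []
        for seed in range(10):
            truth = oe.generate_clean_bscan(cfg, 500 + seed)
            s = oe.simulate_averaged_scan(truth, 9, spec, 600 + seed)
            w = default_windows(truth.clean)
            ratios.append(window_snr(s.averaged, w) / window_snr(s.noisy, w))
        assert np.mean(ratios) < 3.0


class TestMakePairedDataset:
    def test_split_bookkeeping(self):
        cfg = oe.DatasetConfig(phantom=oe.PhantomConfig(height=32, width=32))
        data = oe.make_paired_dataset(10, cfg, seed=1)
        assert len(data.train) == 8 and len(data.test) == 2
        seeds = [s.clean.meta["phantom_seed"] for s in data.train + data.test]
        assert len(set(seeds)) == 10

    def test_deterministic(self):
        cfg = oe.DatasetConfig(phantom=oe.PhantomConfig(height=32, width=32))
        a = oe.make_paired_dataset(4, cfg, seed=2)
        b = oe.make_paired_dataset(4, cfg, seed=2)
        for s, t in zip(a.train + a.test, b.train + b.test):
            np.testing.assert_array_equal(s.noisy.pixels, t.noisy.pixels)
            np.testing.assert_array_equal(s.averaged.pixels, t.averaged.pixels)

    def test_samples_satisfy_invariants(self):
        cfg = oe.DatasetConfig(phantom=oe.PhantomConfig(height=32, width=32))
        data = oe.make_paired_dataset(30, cfg, seed=3)
        for s in data.train + data.test:
            assert s.noisy.shape == s.averaged.shape == s.clean.shape
            assert s.n_frames >= 1
            for img in (s.noisy, s.averaged, s.clean):
                img.validate()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigError):
            oe.make_paired_dataset(1, oe.DatasetConfig(), seed=1)
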