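"""Reconstruction loss, training descent, fine-tuning, and distillation."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.metrics import structural_similarity

import octenhance as oe
from octenhance.errors import ConfigError, InputError, OctEnhanceError


def tiny_dataset(n, seed, size=32):
    cfg = oe.DatasetConfig(phantom=oe.PhantomConfig(height=size, width=size))
    data = oe.make_paired_dataset(n, cfg, seed=seed)
    return data.train + data.test


class TestReconstructionLoss:
    def test_zero_at_equality(self, rng):
        x = rng.uniform(0, 1, (24, 24))
        assert oe.reconstruction_loss(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_mae_term_arithmetic(self):
        # MAE of [[0,0],[0,0]] vs [[0.4,0],[0,0]] is 0.1; padded to a
        # constant-elsewhere pair so the SSIM window fits
        out = np.zeros((16, 16))
        tgt = np.zeros((16, 16))
        tgt[0, 0] = 0.4
        assert oe.mae(out, tgt) == pytest.approx(0.4 / 256)

    def test_matches_independent_ssim_plus_mae_oracle(self, rng):
        for _ in range(5):
            a = rng.uniform(0, 1, (32, 32))
            b = np.clip(a + rng.normal(0, 0.1, (32, 32)), 0, 1)
            oracle = np.abs(a - b).mean() + (
                1.0
                - structural_similarity(
                    a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
                    use_sample_covariance=False,
                )
            )
            assert oe.reconstruction_loss(a, b) == pytest.approx(oracle, abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            oe.reconstruction_loss(np.zeros((16, 16)), np.zeros((16, 18)))

    def test_nonnegative_and_symmetric_ssim_term(self, rng):
        a = rng.uniform(0, 1, (24, 24))
        b = rng.uniform(0, 1, (24, 24))
        assert oe.reconstruction_loss(a, b) >= 0
        assert oe.ssim(a, b) == pytest.approx(oe.ssim(b, a), abs=1e-12)


class TestTrainNetwork:
    def test_loss_descends_on_desk_run(self, desk_model):
        _, history = desk_model
        assert len(history) == 15
        assert history[-1] < history[0]

    def test_default_schedule(self):
        cfg = oe.TrainConfig()
        assert cfg.epochs == 500
        assert cfg.learning_rate == pytest.approx(1e-4)

    def test_same_seed_reproduces_history(self):
        data = tiny_dataset(6, seed=21)
        histories = []
        for _ in range(2):
            net = oe.build_network(
                oe.NetworkSpec(family="brunet94", levels=2, base_channels=2), seed=9)
            _, h = oe.train_network(net, data, oe.TrainConfig(
                epochs=2, learning_rate=1e-3, batch_size=4, seed=9))
            histories.append(h)
        assert histories[0] == histories[1]

    def test_empty_dataset_rejected(self):
        net = oe.build_network(
            oe.NetworkSpec(family="brunet94", levels=2, base_channels=2), seed=0)
        with pytest.raises(InputError):
            oe.train_network(net, [], oe.TrainConfig(epochs=1))

    def test_identity_task_is_learnable(self):
        """Training on pairs whose target equals the input drives the loss
        toward zero."""
        data = tiny_dataset(12, seed=31, size=64)
        pairs = [oe.PairedSample(noisy=s.averaged, averaged=s.averaged,
                                 clean=s.clean, n_frames=s.n_frames) for s in data]
        net = oe.build_network(
            oe.NetworkSpec(family="brunet94", levels=2, base_channels=4), seed=13)
        _, h = oe.train_network(net, pairs, oe.TrainConfig(
            epochs=20, learning_rate=3e-3, batch_size=4, seed=13))
        assert h[-1] < 0.25 * h[0]
        assert h[-1] < 0.15


class TestFineTune:
    def test_zero_epochs_is_noop(self):
        net = oe.build_network(
            oe.NetworkSpec(family="brunet94", levels=2, base_channels=2), seed=1)
        before = [p.data.copy() for p in net.parameters]
        _, h = oe.fine_tune(net, tiny_dataset(4, seed=41), oe.TrainConfig(epochs=5), epochs=0)
        assert h == []
        for p, b in zip(net.parameters, before):
            np.testing.assert_array_equal(p.data, b)

    def test_fine_tuning_reduces_loss_on_new_set(self):
        set_a = tiny_dataset(8, seed=51)
        set_b = tiny_dataset(8, seed=61)
        net = oe.build_network(
            oe.NetworkSpec(family="brunet94", levels=2, base_channels=4), seed=7)
        cfg = oe.TrainConfig(epochs=4, learning_rate=2e-3, batch_size=4, seed=7)
        oe.train_network(net, set_a, cfg)
        val = set_b[-2:]
        loss_pre = np.mean([
            oe.reconstruction_loss(net.enhance_array(s.noisy.pixels), s.averaged.pixels)
            for s in val])
        oe.fine_tune(net, set_b[:-2], cfg, epochs=6)
        loss_post = np.mean([
            oe.reconstruction_loss(net.enhance_array(s.noisy.pixels), s.averaged.pixels)
            for s in val])
        assert loss_post < loss_pre

    def test_four_variant_ensemble_recipe_expressible(self):
        """The full-scale member recipe is {no fine-tune, fine-tune(A),
        fine-tune(B), fine-tune(A+B)} from one base network."""
        base = tiny_dataset(6, seed=71)
        set_a = tiny_dataset(4, seed=81)
        set_b = tiny_dataset(4, seed=91)
        spec = oe.NetworkSpec(family="brunet94", levels=2, base_channels=2)
        cfg = oe.TrainConfig(epochs=1, learning_rate=1e-3, batch_size=4, seed=3)
        members = []
        for extra in (None, set_a, set_b, set_a + set_b):
            net = oe.build_network(spec, seed=3)
            oe.train_network(net, base, cfg)
            if extra is not None:
                oe.fine_tune(net, extra, cfg, epochs=1)
            members.append(net)
        ens = oe.Ensemble(members=members, use_histeq=True)
        assert ens.variant_count == 8


class TestDistillation:
    def make_grid(self, n_arch, n_noise, datasets):
        archs = tuple(
            oe.NetworkSpec(family=f, levels=2, base_channels=2,
                           skip_mode="concat" if f == "unet" else "sum",
                           pyramid_inject=f != "unet")
            for f in ("brunet94", "unet")[:n_arch]
        )
        noises = tuple(
            oe.NoiseSpec(model=m, sigma=s)
            for m, s in (("gaussian", 0.1), ("rayleigh", 0.05))[:n_noise]
        )
        tiers = (oe.distillation_tiers(noises[0])[0],)
        return oe.DistillGrid(architectures=archs, datasets=datasets,
                              noise_models=noises, augmentation_tiers=tiers)

    def test_single_cell_grid_reproduces_member_predictions(self):
        data = tiny_dataset(4, seed=101)
        grid = self.make_grid(1, 1, (("d0", data),))
        cfg = oe.TrainConfig(epochs=1, learning_rate=1e-3, batch_size=4, seed=17)
        out = oe.distill_synthetic_set(grid, data, cfg)
        net = oe.build_network(grid.architectures[0], seed=17)
        oe.train_network(net, data, oe.TrainConfig(
            epochs=1, learning_rate=1e-3, batch_size=4, seed=17,
            augmentation=oe.distillation_tiers(grid.noise_models[0])[0]))
        for s_out, s_in in zip(out, data):
            np.testing.assert_allclose(
                s_out.averaged.pixels, net.enhance_array(s_in.noisy.pixels), atol=1e-12)

    def test_identical_cells_average_to_member(self):
        data = tiny_dataset(4, seed=111)
        # two cells identical up to the dataset tag: the mean of equal
        # predictions equals either cell's predictions
        grid2 = self.make_grid(1, 1, (("d0", data), ("d0b", data)))
        grid1 = self.make_grid(1, 1, (("d0", data),))
        cfg = oe.TrainConfig(epochs=1, learning_rate=1e-3, batch_size=4, seed=23)
        out2 = oe.distill_synthetic_set(grid2, data, cfg)
        out1 = oe.distill_synthetic_set(grid1, data, cfg)
        assert len(out2) == len(data)
        for a, b in zip(out2, out1):
            np.testing.assert_allclose(a.averaged.pixels, b.averaged.pixels, atol=1e-12)

    def test_toy_grid_denoises_the_targets(self):
        data = tiny_dataset(25, seed=121)
        base = data[:20]
        grid = self.make_grid(2, 2, (("d0", base),))  # 2x1x2x1 = 4 networks
        cfg = oe.TrainConfig(epochs=3, learning_rate=2e-3, batch_size=4, seed=29)
        out = oe.distill_synthetic_set(grid, base, cfg)
        assert len(out) == len(base)
        quieter = sum(
            oe.immerkaer_noise(s.averaged) <= oe.immerkaer_noise(s.noisy) for s in out
        )
        assert quieter >= 0.8 * len(out)

    def test_empty_grid_axis_rejected(self):
        with pytest.raises(ConfigError):
            oe.DistillGrid(architectures=(), datasets=(("d", []),),
                           noise_models=(oe.NoiseSpec(),),
                           augmentation_tiers=(oe.AugmentationConfig(),))
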