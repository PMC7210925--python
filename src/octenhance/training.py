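"""Reconstruction loss, training loop, fine-tuning, and multi-network
distillation.

The loss is MAE + (1 - SSIM) between the network output and the N-frame
averaged target. SSIM enters as (1 - SSIM): the structural similarity is
to be maximized, so the standard SSIM loss term is used. Optimization is
mini-batch Adam; augmentations are redrawn once per mini-batch, with
geometric transforms applied jointly to input and target and the
corruptions (noise, intensity, blur) applied to the input only, so the
network learns to undo them.

Distillation trains one small network per grid cell
(architecture x dataset x noise model x augmentation tier), applies every
trained network to each base image, and averages the predictions into the
targets of a new synthetic training set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from . import _engine as eng
from .augment import AugmentationConfig, sample_augmentation
from .bscan import BScan
from .errors import ConfigError, InputError, OctEnhanceError
from .networks import EnhancementNetwork, NetworkSpec, build_network
from .phantom import NoiseSpec, PairedSample

# SSIM window identical to the evaluation metric: 11x11 Gaussian,
# sigma 1.5, K1=0.01, K2=0.03, dynamic range 1
_SSIM_SIGMA = 1.5
_SSIM_RADIUS = 5
_SSIM_KERNEL = eng.gaussian_kernel1d(_SSIM_SIGMA, _SSIM_RADIUS)
_C1 = 0.01**2
_C2 = 0.03**2


def ssim_graph(x: eng.Tensor, y: eng.Tensor) -> eng.Tensor:
    """Differentiable mean local SSIM over an (N, C, H, W) batch."""

    def f(t: eng.Tensor) -> eng.Tensor:
        return eng.sepfilter2d(t, _SSIM_KERNEL)

    ux, uy = f(x), f(y)
    vx = eng.sub(f(eng.mul(x, x)), eng.mul(ux, ux))
    vy = eng.sub(f(eng.mul(y, y)), eng.mul(uy, uy))
    vxy = eng.sub(f(eng.mul(x, y)), eng.mul(ux, uy))
    num = eng.mul(2.0 * eng.mul(ux, uy) + _C1, 2.0 * vxy + _C2)
    den = eng.mul(eng.mul(ux, ux) + eng.mul(uy, uy) + _C1, vx + vy + _C2)
    return eng.mean(eng.crop_border(eng.div(num, den), _SSIM_RADIUS))


def loss_graph(output: eng.Tensor, target: eng.Tensor) -> eng.Tensor:
    """MAE + (1 - SSIM), differentiable."""
    l1 = eng.mean(eng.absolute(eng.sub(output, target)))
    return eng.add(l1, eng.sub(eng.Tensor(1.0), ssim_graph(output, target)))


def reconstruction_loss(output: BScan | np.ndarray, target: BScan | np.ndarray) -> float:
    """MAE(output, target) + (1 - SSIM(output, target)).

    Nonnegative; zero iff the images are equal.
    """
    a = output.pixels if isinstance(output, BScan) else np.asarray(output, dtype=np.float64)
    b = target.pixels if isinstance(target, BScan) else np.asarray(target, dtype=np.float64)
    if a.shape != b.shape:
        raise InputError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(loss_graph(eng.Tensor(a[None, None]), eng.Tensor(b[None, None])).data)


class Adam:
    """Adaptive-moment gradient descent (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[eng.Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule; defaults follow the full-scale recipe
    (500 epochs, Adam at 1e-4). Desk-scale runs override both."""

    epochs: int = 500
    learning_rate: float = 1e-4
    batch_size: int = 8
    augmentation: AugmentationConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ConfigError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ConfigError(f"batch_size must be >= 1, got {self.batch_size}")


def _stack(samples: list[PairedSample]) -> tuple[np.ndarray, np.ndarray]:
    shapes = {s.noisy.shape for s in samples}
    if len(shapes) != 1:
        raise InputError(f"mini-batch mixes image shapes: {sorted(shapes)}")
    x = np.stack([s.noisy.pixels for s in samples])[:, None]
    t = np.stack([s.averaged.pixels for s in samples])[:, None]
    return x, t


def _run_training(
    network: EnhancementNetwork,
    dataset: list[PairedSample],
    config: TrainConfig,
    epochs: int,
) -> list[float]:
    if not dataset:
        raise InputError("training dataset is empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(network.parameters, lr=config.learning_rate)
    history: list[float] = []
    n = len(dataset)
    for epoch in range(epochs):
        order = rng.permutation(n)
        batch_losses: list[float] = []
        for start in range(0, n, config.batch_size):
            batch = [dataset[i] for i in order[start : start + config.batch_size]]
            x, t = _stack(batch)
            if config.augmentation is not None and config.augmentation.p_apply > 0:
                draw = sample_augmentation(config.augmentation, rng)
                for i in range(len(batch)):
                    x[i, 0], t[i, 0] = draw.apply_pair(x[i, 0], t[i, 0], salt=i)
            network.zero_grad()
            out = network.forward_batch(x)
            loss = loss_graph(out, eng.Tensor(t))
            val = float(loss.data)
            if not np.isfinite(val):
                raise OctEnhanceError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            loss.backward()
            opt.step()
            batch_losses.append(val)
        history.append(float(np.mean(batch_losses)))
    return history


def train_network(
    network: EnhancementNetwork,
    dataset: list[PairedSample],
    config: TrainConfig,
) -> tuple[EnhancementNetwork, list[float]]:
    """Train in place; returns the network and the per-epoch mean loss
    (exactly ``config.epochs`` entries). Reproducible per config.seed under
    single-threaded execution."""
    history = _run_training(network, dataset, config, config.epochs)
    return network, history


def fine_tune(
    network: EnhancementNetwork,
    dataset: list[PairedSample],
    config: TrainConfig,
    epochs: int | None = None,
) -> tuple[EnhancementNetwork, list[float]]:
    """Continue training from the current parameters on a new dataset.

    ``epochs=0`` is a no-op returning the network unchanged.
    """
    n_epochs = config.epochs if epochs is None else epochs
    if n_epochs == 0:
        return network, []
    history = _run_training(network, dataset, config, n_epochs)
    return network, history


def distillation_tiers(noise: NoiseSpec) -> list[AugmentationConfig]:
    """The three augmentation tiers of the distillation grid:
    noise; noise + intensity; noise + intensity + geometric."""
    base = dict(noise=noise, enable_blur=False)
    return [
        AugmentationConfig(**base, enable_intensity=False, enable_geometric=False),
        AugmentationConfig(**base, enable_geometric=False),
        AugmentationConfig(**base),
    ]


@dataclass(frozen=True)
class DistillGrid:
    """Cartesian grid of training conditions for distillation. The grid in
    the full-scale recipe is 4 architectures x 3 datasets x 2 noise models
    x 3 augmentation tiers = 72 networks; desk-scale grids are small."""

    architectures: tuple[NetworkSpec, ...]
    datasets: tuple[tuple, ...]  # (tag, list[PairedSample]) pairs
    noise_models: tuple[NoiseSpec, ...]
    augmentation_tiers: tuple[AugmentationConfig, ...]

    def __post_init__(self) -> None:
        for name in ("architectures", "datasets", "noise_models", "augmentation_tiers"):
            if not getattr(self, name):
                raise ConfigError(f"distillation grid has empty {name}")

    @property
    def size(self) -> int:
        return (len(self.architectures) * len(self.datasets)
                * len(self.noise_models) * len(self.augmentation_tiers))


def distill_synthetic_set(
    grid: DistillGrid,
    base_dataset: list[PairedSample],
    config: TrainConfig,
) -> list[PairedSample]:
    """Train one network per grid cell, apply each to every base image, and
    average the predictions into the targets of a new synthetic set."""
    if not base_dataset:
        raise InputError("base dataset is empty")
    cells = list(itertools.product(
        range(len(grid.architectures)),
        range(len(grid.datasets)),
        range(len(grid.noise_models)),
        range(len(grid.augmentation_tiers)),
    ))
    preds = np.zeros((len(base_dataset),) + base_dataset[0].noisy.shape)
    for idx, (ai, di, ni, ti) in enumerate(cells):
        tag = grid.datasets[di][0]
        cell_name = f"(arch={grid.architectures[ai].family}, dataset={tag}, " \
                    f"noise={grid.noise_models[ni].model}, tier={ti})"
        try:
            # every cell trains from the same seed: cells differ only
            # through their declared settings, so duplicated cells yield
            # identical networks
            aug = replace(grid.augmentation_tiers[ti], noise=grid.noise_models[ni])
            cell_cfg = replace(config, augmentation=aug)
            net = build_network(grid.architectures[ai], seed=cell_cfg.seed)
            train_network(net, list(grid.datasets[di][1]), cell_cfg)
        except Exception as exc:  # noqa: BLE001 - cell identity matters to the caller
            raise OctEnhanceError(f"distillation cell {cell_name} failed to train: {exc}") from exc
        for j, sample in enumerate(base_dataset):
            preds[j] += net.enhance_array(sample.noisy.pixels)
    preds /= len(cells)
    out = []
    for j, sample in enumerate(base_dataset):
        distilled = sample.noisy.with_pixels(np.clip(preds[j], 0.0, 1.0), distilled=True)
        out.append(PairedSample(noisy=sample.noisy, averaged=distilled,
                                clean=sample.clean, n_frames=sample.n_frames))
    return out
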