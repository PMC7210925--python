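"""Synthetic layered retinal B-scan phantoms and N-frame averaging.

Real training data for OCT enhancement consists of noisy single frames
paired with registered N-frame averages. This module emulates that setup
at desk scale: a phantom retina is rendered as a stack of smooth
horizontal bands (one bright RPE-like band), with vessel shadows cast
downward and exponential choroid-like decay below the deepest boundary.
Repeated frames are corrupted with (optionally correlated) noise and
integer-pixel fixation jitter, then averaged, yielding
(noisy, averaged, clean) triplets.

Noise is additive by default, matching the corruption models used for
training augmentation; a multiplicative speckle-style option sits behind
a flag. With uncorrelated noise and no jitter the averaged frame obeys
the sqrt(N) SNR law; correlation or jitter lowers the gain, mirroring the
practical ceiling of frame averaging on real devices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .bscan import BScan
from .errors import ConfigError

#: default noise scales for the two corruption models
DEFAULT_GAUSSIAN_SIGMA = 0.5
DEFAULT_RAYLEIGH_SIGMA = 0.2


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic corruption model for a single frame.

    ``correlation`` is the fraction of noise energy shared between
    repeated frames of the same scan; ``jitter_px`` the amplitude of
    integer lateral fixation jitter.
    """

    model: Literal["gaussian", "rayleigh"] = "gaussian"
    sigma: float | None = None  # None -> model default (0.5 / 0.2)
    correlation: float = 0.0
    jitter_px: int = 0
    multiplicative: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "rayleigh"):
            raise ConfigError(f"unknown noise model {self.model!r}")
        if self.sigma is not None and self.sigma < 0:
            raise ConfigError(f"sigma must be >= 0, got {self.sigma}")
        if not 0.0 <= self.correlation <= 1.0:
            raise ConfigError(f"correlation must be in [0, 1], got {self.correlation}")
        if self.jitter_px < 0:
            raise ConfigError(f"jitter_px must be >= 0, got {self.jitter_px}")

    @property
    def effective_sigma(self) -> float:
        if self.sigma is not None:
            return self.sigma
        return DEFAULT_GAUSSIAN_SIGMA if self.model == "gaussian" else DEFAULT_RAYLEIGH_SIGMA


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and reflectivity of the rendered phantom retina."""

    height: int = 64
    width: int = 64
    n_layers: int = 6
    background: float = 0.15       # vitreous intensity above the retina
    reflectivity_range: tuple[float, float] = (0.25, 0.55)
    bright_band: float = 0.85      # RPE-like band intensity
    choroid_reflectivity: float = 0.45
    attenuation_rate: float = 0.06  # per-row decay below the deepest boundary
    edge_softness: float = 1.0      # sigmoid width of band edges, pixels
    curvature: float = 0.08         # foveal dip depth as a fraction of height
    wiggle_amplitude: float = 1.5   # per-boundary smooth variation, pixels
    n_vessels: int = 2
    vessel_width_range: tuple[float, float] = (1.5, 4.0)
    vessel_shadow: float = 0.5      # fractional darkening under a vessel

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ConfigError(f"dimensions must be positive, got {self.height}x{self.width}")
        if self.n_layers < 2:
            raise ConfigError(f"need at least 2 layers, got {self.n_layers}")
        if self.n_vessels < 0:
            raise ConfigError(f"vessel count must be >= 0, got {self.n_vessels}")


@dataclass
class PhantomTruth:
    """A clean phantom together with the geometry that generated it."""

    clean: BScan
    boundaries: np.ndarray            # (n_layers + 1, width) row indices, non-crossing
    layer_reflectivities: np.ndarray  # (n_layers,)
    vessel_columns: list[tuple[float, float]]  # (center column, width)
    attenuation_rate: float
    config: PhantomConfig

    def __post_init__(self) -> None:
        if np.any(np.diff(self.boundaries, axis=0) < 0):
            raise ConfigError("boundary curves cross")
        if len(self.layer_reflectivities) != self.boundaries.shape[0] - 1:
            raise ConfigError("reflectivity count does not match layer count")


@dataclass
class PairedSample:
    """One (noisy frame, N-frame average, clean) supervised triplet."""

    noisy: BScan
    averaged: BScan
    clean: BScan
    n_frames: int

    def __post_init__(self) -> None:
        if not (self.noisy.shape == self.averaged.shape == self.clean.shape):
            raise ConfigError("paired images must share dimensions")
        if self.n_frames < 1:
            raise ConfigError(f"n_frames must be >= 1, got {self.n_frames}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def render_truth(
    boundaries: np.ndarray,
    reflectivities: np.ndarray,
    vessels: list[tuple[float, float]],
    cfg: PhantomConfig,
) -> np.ndarray:
    """Render the clean image from its geometric description (vectorized)."""
    h, w = cfg.height, cfg.width
    rows = np.arange(h, dtype=np.float64)[:, None]
    img = np.full((h, w), cfg.background)
    s = cfg.edge_softness
    for k in range(len(reflectivities)):
        band = _sigmoid((rows - boundaries[k][None, :]) / s) - _sigmoid(
            (rows - boundaries[k + 1][None, :]) / s
        )
        img += (reflectivities[k] - cfg.background) * band
    deepest = boundaries[-1][None, :]
    depth = rows - deepest
    img += (
        (cfg.choroid_reflectivity - cfg.background)
        * _sigmoid(depth / s)
        * np.exp(-cfg.attenuation_rate * np.maximum(depth, 0.0))
    )
    if vessels:
        cols = np.arange(w, dtype=np.float64)[None, :]
        # vessels sit in the inner retina and shadow everything beneath
        vessel_top = boundaries[min(2, len(boundaries) - 1)][None, :]
        below = _sigmoid((rows - vessel_top) / s)
        for center, width in vessels:
            profile = cfg.vessel_shadow * np.exp(-0.5 * ((cols - center) / width) ** 2)
            img *= 1.0 - profile * below
    return np.clip(img, 0.0, 1.0)


def generate_clean_bscan(config: PhantomConfig, seed: int) -> PhantomTruth:
    """Generate one clean phantom; a pure function of (config, seed)."""
    rng = np.random.default_rng(seed)
    h, w = config.height, config.width
    cols = np.arange(w, dtype=np.float64)
    u = (cols - w / 2.0) / w

    def smooth_curve(amp: float) -> np.ndarray:
        # low-order cosine mixture: smooth, band-limited lateral variation
        out = np.zeros(w)
        for _ in range(3):
            freq = rng.uniform(0.5, 2.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            out += rng.uniform(-amp, amp) * np.cos(2.0 * np.pi * freq * cols / w + phase)
        return out

    top = 0.25 * h + config.curvature * h * (4.0 * u**2) + smooth_curve(config.wiggle_amplitude)
    span = 0.45 * h  # retina occupies the middle of the frame
    raw_thick = rng.uniform(0.5, 1.5, size=config.n_layers)
    thick = raw_thick / raw_thick.sum() * span
    boundaries = np.empty((config.n_layers + 1, w))
    boundaries[0] = top
    for k in range(config.n_layers):
        wiggle = smooth_curve(config.wiggle_amplitude * 0.5)
        # keep thickness strictly positive so boundaries never cross
        layer = np.maximum(thick[k] + wiggle, 0.5)
        boundaries[k + 1] = boundaries[k] + layer
    boundaries = np.clip(boundaries, 0.0, h - 1.0)
    boundaries = np.maximum.accumulate(boundaries, axis=0)

    lo, hi = config.reflectivity_range
    refl = rng.uniform(lo, hi, size=config.n_layers)
    refl[-1] = config.bright_band  # deepest band is the bright RPE-like one

    vessels: list[tuple[float, float]] = []
    for _ in range(config.n_vessels):
        center = rng.uniform(0.1 * w, 0.9 * w)
        width = rng.uniform(*config.vessel_width_range)
        vessels.append((float(center), float(width)))

    clean = render_truth(boundaries, refl, vessels, config)
    return PhantomTruth(
        clean=BScan(clean, meta={"phantom_seed": seed}),
        boundaries=boundaries,
        layer_reflectivities=refl,
        vessel_columns=vessels,
        attenuation_rate=config.attenuation_rate,
        config=config,
    )


def _draw_field(shape: tuple[int, int], spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    sigma = spec.effective_sigma
    if spec.model == "gaussian":
        return rng.normal(0.0, sigma, size=shape) if sigma > 0 else np.zeros(shape)
    return rng.rayleigh(sigma, size=shape) if sigma > 0 else np.zeros(shape)


def _corrupt(clean: np.ndarray, fld: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    if spec.multiplicative:
        if spec.model == "gaussian":
            return np.clip(clean * (1.0 + fld), 0.0, 1.0)
        mean = spec.effective_sigma * np.sqrt(np.pi / 2.0)
        unit = fld / mean if mean > 0 else np.ones_like(fld)
        return np.clip(clean * unit, 0.0, 1.0)
    return np.clip(clean + fld, 0.0, 1.0)


def add_noise(img: BScan, spec: NoiseSpec, seed: int) -> BScan:
    """Corrupt one image with the named noise model; deterministic per seed.

    Rayleigh noise is added as drawn (mean-uncentered: its support is
    nonnegative, so it brightens the image on average).
    """
    rng = np.random.default_rng(seed)
    fld = _draw_field(img.shape, spec, rng)
    return img.with_pixels(_corrupt(img.pixels, fld, spec), noise_model=spec.model,
                           noise_sigma=spec.effective_sigma, noise_seed=seed)


def _lateral_shift(a: np.ndarray, dx: int) -> np.ndarray:
    """Shift columns by dx with edge replication."""
    if dx == 0:
        return a
    idx = np.clip(np.arange(a.shape[1]) - dx, 0, a.shape[1] - 1)
    return a[:, idx]


def simulate_averaged_scan(
    truth: PhantomTruth, n_frames: int, spec: NoiseSpec, seed: int
) -> PairedSample:
    """Draw ``n_frames`` corrupted frames of one phantom and average them.

    Each frame's noise mixes a shared component (weight sqrt(correlation))
    with an independent draw (weight sqrt(1 - correlation)); the mixture
    preserves the marginal for the Gaussian model. Each frame is laterally
    shifted by an integer jitter within +/- jitter_px before averaging.
    The first frame is returned as ``noisy``.
    """
    if n_frames < 1:
        raise ConfigError(f"n_frames must be >= 1, got {n_frames}")
    rng = np.random.default_rng(seed)
    clean = truth.clean.pixels
    shared = _draw_field(clean.shape, spec, rng)
    wc = np.sqrt(spec.correlation)
    wi = np.sqrt(1.0 - spec.correlation)
    frames = []
    for _ in range(n_frames):
        indep = _draw_field(clean.shape, spec, rng)
        fld = wc * shared + wi * indep
        dx = int(rng.integers(-spec.jitter_px, spec.jitter_px + 1)) if spec.jitter_px else 0
        frames.append(_corrupt(_lateral_shift(clean, dx), fld, spec))
    averaged = np.mean(frames, axis=0)
    meta = {"n_frames": n_frames, "noise_model": spec.model,
            "noise_sigma": spec.effective_sigma, "seed": seed}
    return PairedSample(
        noisy=truth.clean.with_pixels(frames[0], **meta),
        averaged=truth.clean.with_pixels(averaged, **meta),
        clean=truth.clean,
        n_frames=n_frames,
    )


@dataclass(frozen=True)
class DatasetConfig:
    """Study conditions for a paired phantom dataset.

    Defaults emulate the evaluation data: 9-times-averaged targets and
    moderate additive Gaussian noise on each frame.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(model="gaussian", sigma=0.1))
    n_frames: int = 9
    split: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.split < 1.0:
            raise ConfigError(f"split must be in (0, 1), got {self.split}")
        if self.n_frames < 1:
            raise ConfigError(f"n_frames must be >= 1, got {self.n_frames}")


@dataclass
class PhantomDataset:
    train: list[PairedSample]
    test: list[PairedSample]

    def __len__(self) -> int:
        return len(self.train) + len(self.test)


def make_paired_dataset(n_samples: int, config: DatasetConfig, seed: int) -> PhantomDataset:
    """Generate ``n_samples`` independent phantoms, simulate averaging for
    each, and split train/test disjointly by phantom."""
    if n_samples < 2:
        raise ConfigError(f"need at least 2 samples, got {n_samples}")
    state = np.random.SeedSequence(seed).generate_state(2 * n_samples)
    samples = []
    for i in range(n_samples):
        truth = generate_clean_bscan(config.phantom, int(state[2 * i]) % (2**31))
        samples.append(
            simulate_averaged_scan(truth, config.n_frames, config.noise,
                                   int(state[2 * i + 1]) % (2**31))
        )
    n_train = int(round(config.split * n_samples))
    n_train = min(max(n_train, 1), n_samples - 1)
    return PhantomDataset(train=samples[:n_train], test=samples[n_train:])
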