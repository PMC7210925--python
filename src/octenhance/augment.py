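"""On-the-fly stochastic corruption of network inputs during training.

Four augmentations, each activated independently with probability
``p_apply`` and applied in the fixed order

    noise -> intensity (a*x**g + b) -> geometric (rotate, scale) -> blur.

Parameters are drawn once per training mini-batch; the drawn record is
returned alongside the transform so an augmentation can be logged and
replayed bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bscan import BScan
from .errors import ConfigError
from .phantom import NoiseSpec, _corrupt, _draw_field


def intensity_transform(img: np.ndarray | BScan, a: float, b: float, g: float) -> np.ndarray:
    """Brightness/contrast/gamma manipulation clip(a * img**g + b, 0, 1)."""
    if g <= 0:
        raise ConfigError(f"gamma must be > 0, got {g}")
    x = img.pixels if isinstance(img, BScan) else np.asarray(img, dtype=np.float64)
    return np.clip(a * np.power(x, g) + b, 0.0, 1.0)


def geometric_transform(img: np.ndarray | BScan, r: float, s: float) -> np.ndarray:
    """Rotate by ``r`` degrees and rescale by ``s`` about the image center,
    resampled bilinearly onto the original grid with reflect padding.

    ``r == 0`` and ``s == 1`` short-circuits to the exact input.
    """
    if s <= 0:
        raise ConfigError(f"scale must be > 0, got {s}")
    x = img.pixels if isinstance(img, BScan) else np.asarray(img, dtype=np.float64)
    if r == 0.0 and s == 1.0:
        return x.copy()
    theta = np.deg2rad(r)
    c, sn = np.cos(theta), np.sin(theta)
    # inverse map: output grid -> input grid
    minv = np.array([[c, -sn], [sn, c]]) / s
    center = (np.asarray(x.shape, dtype=np.float64) - 1.0) / 2.0
    offset = center - minv @ center
    out = ndimage.affine_transform(x, minv, offset=offset, order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def gaussian_blur(img: np.ndarray | BScan, sigma: float) -> np.ndarray:
    """Isotropic Gaussian blur with reflect boundary; sigma 0 is identity."""
    if sigma < 0:
        raise ConfigError(f"blur sigma must be >= 0, got {sigma}")
    x = img.pixels if isinstance(img, BScan) else np.asarray(img, dtype=np.float64)
    if sigma == 0:
        return x.copy()
    return ndimage.gaussian_filter(x, sigma=sigma, mode="reflect")


@dataclass(frozen=True)
class AugmentationConfig:
    """Intervals and activation probability of the corruption pipeline."""

    a_range: tuple[float, float] = (0.5, 1.5)
    b_range: tuple[float, float] = (0.5, 1.5)
    g_range: tuple[float, float] = (0.5, 1.5)
    r_range: tuple[float, float] = (-45.0, 45.0)   # degrees
    s_range: tuple[float, float] = (0.5, 1.5)      # scale fraction
    blur_sigma: float = 1.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    p_apply: float = 0.5
    # eligibility switches: a disabled stage is never activated, letting the
    # distillation grid express its noise / noise+intensity /
    # noise+intensity+geometric tiers
    enable_noise: bool = True
    enable_intensity: bool = True
    enable_geometric: bool = True
    enable_blur: bool = True

    def __post_init__(self) -> None:
        for name in ("a_range", "b_range", "g_range", "r_range", "s_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} has lower > upper: ({lo}, {hi})")
        if not 0.0 <= self.p_apply <= 1.0:
            raise ConfigError(f"p_apply must be in [0, 1], got {self.p_apply}")
        if self.blur_sigma < 0:
            raise ConfigError(f"blur_sigma must be >= 0, got {self.blur_sigma}")

    @classmethod
    def disabled(cls) -> "AugmentationConfig":
        return cls(p_apply=0.0)


@dataclass(frozen=True)
class AugmentationDraw:
    """One sampled parameter set; replaying it reproduces the output
    bit-identically (the noise field is keyed by ``noise_seed + salt``)."""

    noise_active: bool
    intensity_active: bool
    geometric_active: bool
    blur_active: bool
    a: float
    b: float
    g: float
    r: float
    s: float
    blur_sigma: float
    noise: NoiseSpec
    noise_seed: int

    def apply(self, img: np.ndarray | BScan, salt: int = 0) -> np.ndarray:
        """Full pipeline in the fixed order noise->intensity->geometric->blur."""
        x = img.pixels if isinstance(img, BScan) else np.asarray(img, dtype=np.float64)
        x = self._corrupt_only(x, salt)
        if self.geometric_active:
            x = geometric_transform(x, self.r, self.s)
        if self.blur_active:
            x = gaussian_blur(x, self.blur_sigma)
        return x

    def apply_pair(
        self, inp: np.ndarray, target: np.ndarray, salt: int = 0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Supervised variant: corruptions (noise, intensity, blur) hit the
        input only; the geometric transform is applied jointly to input and
        target with the same drawn parameters."""
        x = self._corrupt_only(np.asarray(inp, dtype=np.float64), salt)
        t = np.asarray(target, dtype=np.float64)
        if self.geometric_active:
            x = geometric_transform(x, self.r, self.s)
            t = geometric_transform(t, self.r, self.s)
        if self.blur_active:
            x = gaussian_blur(x, self.blur_sigma)
        return x, t

    def _corrupt_only(self, x: np.ndarray, salt: int) -> np.ndarray:
        if self.noise_active:
            rng = np.random.default_rng((self.noise_seed + salt) % (2**31))
            x = _corrupt(x, _draw_field(x.shape, self.noise, rng), self.noise)
        if self.intensity_active:
            x = intensity_transform(x, self.a, self.b, self.g)
        return x


def sample_augmentation(
    config: AugmentationConfig, rng: np.random.Generator
) -> AugmentationDraw:
    """Draw one augmentation: independent Bernoulli(p_apply) activation per
    stage, uniform parameters from the configured intervals."""
    enabled = np.array([config.enable_noise, config.enable_intensity,
                        config.enable_geometric, config.enable_blur])
    active = (rng.random(4) < config.p_apply) & enabled
    return AugmentationDraw(
        noise_active=bool(active[0]),
        intensity_active=bool(active[1]),
        geometric_active=bool(active[2]),
        blur_active=bool(active[3]),
        a=float(rng.uniform(*config.a_range)),
        b=float(rng.uniform(*config.b_range)),
        g=float(rng.uniform(*config.g_range)),
        r=float(rng.uniform(*config.r_range)),
        s=float(rng.uniform(*config.s_range)),
        blur_sigma=config.blur_sigma,
        noise=config.noise,
        noise_seed=int(rng.integers(0, 2**31)),
    )
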