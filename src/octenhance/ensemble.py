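"""Test-time ensemble enhancement.

Each member network is applied to the unmodified input and, optionally,
to a histogram-equalized variant; the enhanced image is the unweighted
pixel-wise mean of all variant outputs. Four members with equalization on
yields the eight-way mean used at full scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import exposure

from .bscan import BScan
from .errors import ConfigError, OctEnhanceError
from .networks import EnhancementNetwork


def histogram_equalize(img: BScan | np.ndarray) -> np.ndarray:
    """Global 256-bin histogram equalization mapping to [0, 1].

    Constant images are returned unchanged (their histogram carries no
    contrast to redistribute).
    """
    x = img.pixels if isinstance(img, BScan) else np.asarray(img, dtype=np.float64)
    if x.max() == x.min():
        return x.copy()
    return exposure.equalize_hist(x, nbins=256)


@dataclass
class Ensemble:
    """A bag of trained networks applied jointly at inference time."""

    members: list[EnhancementNetwork] = field(default_factory=list)
    use_histeq: bool = True

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError("ensemble needs at least one member")

    @property
    def variant_count(self) -> int:
        return len(self.members) * (2 if self.use_histeq else 1)

    def enhance(self, img: BScan) -> BScan:
        return ensemble_enhance(self, img)


def ensemble_enhance(ensemble: Ensemble, img: BScan) -> BScan:
    """Pixel-wise mean over every (member, input-variant) output, clipped
    to [0, 1]. Invariant to member ordering."""
    img.validate()
    variants = [img.pixels]
    if ensemble.use_histeq:
        variants.append(histogram_equalize(img))
    acc = np.zeros(img.shape)
    count = 0
    for member in ensemble.members:
        for v in variants:
            out = member.enhance_array(v)
            if out.shape != img.shape:
                raise OctEnhanceError(
                    f"member produced shape {out.shape}, expected {img.shape}"
                )
            acc += out
            count += 1
    return img.with_pixels(np.clip(acc / count, 0.0, 1.0),
                           enhanced=True, ensemble_variants=count)
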