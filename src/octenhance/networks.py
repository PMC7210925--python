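"""Pyramid encoder-decoder enhancement networks.

Four architecture families are provided, all mapping a single-channel
B-scan to an enhanced B-scan of the same size and range:

* ``unet`` — standard U-net: two 3x3 conv+ReLU blocks per level,
  concatenation skip connections, upsampling by either 2x2 stride-2
  transposed convolution or bilinear interpolation followed by a 1x1
  channel-mixing convolution.
* ``brunet`` — branch-residual pyramid variant: the 2^k-downsampled
  input image is injected as an extra channel at each encoder level,
  skips are summed rather than concatenated, and each level carries a
  single 3x3 conv block.
* ``brunet94`` — the refined variant: two back-to-back 3x3 conv blocks
  per pyramid level on both the downsampling and upsampling paths, an
  extra horizontal block between the paths at the coarsest level, input
  pyramid injection, and summation skips.

Channels double per level (base, 2*base, 4*base, ...). Downsampling is
2x2 average pooling. The output head is a 1x1 convolution clamped to
[0, 1]. Inputs whose sides are not divisible by 2^(levels-1) are
reflect-padded before the pass and the output is cropped back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from . import _engine as eng
from .bscan import BScan
from .errors import ConstructionError, InputError

Family = Literal["unet", "brunet", "brunet94"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description; a checkpoint embeds its spec so trained
    weights are self-describing."""

    family: Family = "brunet94"
    levels: int = 4
    base_channels: int = 16
    upsampling: Literal["transposed", "bilinear"] = "bilinear"
    skip_mode: Literal["sum", "concat"] = "sum"
    pyramid_inject: bool = True
    alternate_sum_skips: bool = False  # literal "every other" skip reading
    # Optional per-level override of decoder up-transition output channels;
    # None mirrors the encoder. Mismatched overrides under sum skips fail
    # at construction.
    up_channels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("unet", "brunet", "brunet94"):
            raise ConstructionError(f"unknown family {self.family!r}")
        if self.levels < 2:
            raise ConstructionError(f"levels must be >= 2, got {self.levels}")
        if self.base_channels < 1:
            raise ConstructionError(f"base_channels must be >= 1, got {self.base_channels}")
        if self.upsampling not in ("transposed", "bilinear"):
            raise ConstructionError(f"unknown upsampling {self.upsampling!r}")
        if self.family in ("brunet", "brunet94") and self.skip_mode != "sum":
            raise ConstructionError(f"family {self.family!r} requires skip_mode='sum'")
        if self.family == "unet" and self.skip_mode != "concat":
            raise ConstructionError("family 'unet' requires skip_mode='concat'")
        if self.up_channels is not None and len(self.up_channels) != self.levels - 1:
            raise ConstructionError(
                f"up_channels needs {self.levels - 1} entries, got {len(self.up_channels)}"
            )

    @property
    def blocks_per_level(self) -> int:
        return 1 if self.family == "brunet" else 2

    @property
    def has_horizontal_block(self) -> bool:
        return self.family == "brunet94"

    def channels(self, level: int) -> int:
        return self.base_channels * (2**level)

    @classmethod
    def for_family(cls, family: Family, upsampling: str = "bilinear", **kw) -> "NetworkSpec":
        """Spec with the family's forced skip mode and injection default."""
        if family == "unet":
            kw.setdefault("skip_mode", "concat")
            kw.setdefault("pyramid_inject", False)
        else:
            kw.setdefault("skip_mode", "sum")
            kw.setdefault("pyramid_inject", True)
        return cls(family=family, upsampling=upsampling, **kw)


class _Conv:
    """3x3 or 1x1 convolution layer with He-scaled initialization."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias_init: float = 0.0) -> None:
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = eng.Tensor(rng.normal(0.0, std, size=(cout, cin, k, k)), requires_grad=True)
        self.b = eng.Tensor(np.full(cout, bias_init), requires_grad=True)
        self.cin, self.cout = cin, cout

    def __call__(self, x: eng.Tensor) -> eng.Tensor:
        return eng.conv2d(x, self.w, self.b)

    @property
    def params(self) -> list[eng.Tensor]:
        return [self.w, self.b]


class _ConvT:
    """2x2 stride-2 transposed convolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        std = np.sqrt(2.0 / (cin * 4))
        self.w = eng.Tensor(rng.normal(0.0, std, size=(cin, cout, 2, 2)), requires_grad=True)
        self.b = eng.Tensor(np.zeros(cout), requires_grad=True)
        self.cin, self.cout = cin, cout

    def __call__(self, x: eng.Tensor) -> eng.Tensor:
        return eng.conv_transpose2(x, self.w, self.b)

    @property
    def params(self) -> list[eng.Tensor]:
        return [self.w, self.b]


def _conv_block(convs: list[_Conv], x: eng.Tensor) -> eng.Tensor:
    for c in convs:
        x = eng.relu(c(x))
    return x


class EnhancementNetwork:
    """Trainable image-to-image enhancement function."""

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        L = spec.levels
        nb = spec.blocks_per_level
        ch = [spec.channels(k) for k in range(L)]
        inject = spec.pyramid_inject

        self.encoder: list[list[_Conv]] = []
        for k in range(L):
            cin = 1 if k == 0 else ch[k - 1] + (1 if inject else 0)
            convs = [_Conv(cin, ch[k], 3, rng)]
            for _ in range(nb - 1):
                convs.append(_Conv(ch[k], ch[k], 3, rng))
            self.encoder.append(convs)

        self.horizontal: list[_Conv] = []
        if spec.has_horizontal_block:
            self.horizontal = [_Conv(ch[-1], ch[-1], 3, rng) for _ in range(nb)]

        # decoder runs from level L-2 down to 0; index d maps to level L-2-d
        self.up_trans: list[_ConvT | _Conv] = []
        self.decoder: list[list[_Conv]] = []
        self.skip_active: list[bool] = []
        up_ch = list(spec.up_channels) if spec.up_channels is not None else None
        for d in range(L - 1):
            level = L - 2 - d
            # the previous decoder stage (or the coarsest encoder) emits
            # ch[level + 1] channels
            src_ch = ch[level + 1]
            tgt_ch = up_ch[d] if up_ch is not None else ch[level]
            if spec.upsampling == "transposed":
                self.up_trans.append(_ConvT(src_ch, tgt_ch, rng))
            else:
                self.up_trans.append(_Conv(src_ch, tgt_ch, 1, rng))
            active = not (spec.alternate_sum_skips and level % 2 == 1)
            self.skip_active.append(active)
            if active and spec.skip_mode == "sum" and tgt_ch != ch[level]:
                raise ConstructionError(
                    f"sum skip at level {level}: decoder carries {tgt_ch} channels "
                    f"but the encoder skip carries {ch[level]}"
                )
            merged = tgt_ch + (ch[level] if active and spec.skip_mode == "concat" else 0)
            convs = [_Conv(merged, ch[level], 3, rng)]
            for _ in range(nb - 1):
                convs.append(_Conv(ch[level], ch[level], 3, rng))
            self.decoder.append(convs)

        # head biased to mid-gray so the clamped output starts in the
        # interior of [0, 1] and gradients flow from the first step
        self.head = _Conv(ch[0], 1, 1, rng, bias_init=0.5)

    # -- parameters ----------------------------------------------------
    @property
    def parameters(self) -> list[eng.Tensor]:
        ps: list[eng.Tensor] = []
        for blk in self.encoder:
            for c in blk:
                ps.extend(c.params)
        for c in self.horizontal:
            ps.extend(c.params)
        for t in self.up_trans:
            ps.extend(t.params)
        for blk in self.decoder:
            for c in blk:
                ps.extend(c.params)
        ps.extend(self.head.params)
        return ps

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters)

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad = None

    # -- forward -------------------------------------------------------
    def forward_batch(self, x: np.ndarray | eng.Tensor) -> eng.Tensor:
        """Differentiable pass on an (N, 1, H, W) batch with H, W divisible
        by 2^(levels-1)."""
        if not isinstance(x, eng.Tensor):
            x = eng.Tensor(x)
        spec = self.spec
        L = spec.levels
        h, w = x.data.shape[-2:]
        div = 2 ** (L - 1)
        if h % div or w % div:
            raise InputError(f"batch dims {h}x{w} not divisible by {div}")

        # input pyramid for injection
        pyramid = [x]
        for _ in range(L - 1):
            pyramid.append(eng.avg_pool2(pyramid[-1]))

        skips: list[eng.Tensor] = []
        feat = _conv_block(self.encoder[0], x)
        skips.append(feat)
        for k in range(1, L):
            feat = eng.avg_pool2(feat)
            if spec.pyramid_inject:
                feat = eng.concat_channels([feat, pyramid[k]])
            feat = _conv_block(self.encoder[k], feat)
            skips.append(feat)

        if self.horizontal:
            feat = _conv_block(self.horizontal, feat)

        for d in range(L - 1):
            level = L - 2 - d
            trans = self.up_trans[d]
            if spec.upsampling == "transposed":
                feat = trans(feat)
            else:
                feat = trans(eng.upsample_bilinear2(feat))
            if self.skip_active[d]:
                if spec.skip_mode == "sum":
                    feat = eng.add(feat, skips[level])
                else:
                    feat = eng.concat_channels([feat, skips[level]])
            feat = _conv_block(self.decoder[d], feat)

        return eng.clamp01(self.head(feat))

    def enhance(self, img: BScan) -> BScan:
        """Enhance one B-scan; pads/crops non-divisible inputs."""
        img.validate()
        out = self.enhance_array(img.pixels)
        return img.with_pixels(out, enhanced=True, network=self.spec.family)

    def enhance_array(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels, dtype=np.float64)
        if not np.all(np.isfinite(pixels)):
            raise InputError("non-finite input pixels")
        h, w = pixels.shape
        div = 2 ** (self.spec.levels - 1)
        ph = (-h) % div
        pw = (-w) % div
        padded = np.pad(pixels, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else pixels
        out = self.forward_batch(padded[None, None]).data[0, 0]
        return out[:h, :w]

    # -- serialization -------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters)}
        spec_json = json.dumps({**asdict(self.spec), "seed": self.seed})
        np.savez(path, __spec__=np.array(spec_json), **arrays)

    @classmethod
    def load(cls, path: str) -> "EnhancementNetwork":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__spec__"]))
            seed = meta.pop("seed", 0)
            if meta.get("up_channels") is not None:
                meta["up_channels"] = tuple(meta["up_channels"])
            net = cls(NetworkSpec(**meta), seed=seed)
            for i, p in enumerate(net.parameters):
                arr = data[f"p{i}"]
                if arr.shape != p.data.shape:
                    raise InputError(f"checkpoint parameter {i} shape mismatch")
                p.data = arr.astype(np.float64)
        return net


def build_network(spec: NetworkSpec, seed: int = 0) -> EnhancementNetwork:
    """Construct a network with deterministic, seed-controlled weights."""
    return EnhancementNetwork(spec, seed=seed)
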