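"""U-net denoiser with wide-activation blocks and depth-to-space upsampling.

The encoder applies, at each of ``depth`` scales, a wide-activation block —
a 1×1 convolution expanding the channel width by ``expansion``, a ReLU, and
a k×k convolution back to the base width — followed by 2× average-pool
downsampling. The mirrored decoder upsamples with depth-to-space (pixel
shuffle, fed by a 1×1 convolution producing 4× channels), concatenates the
encoder feature map of the matching scale, and applies another wide block.
A final k×k linear convolution produces the single-channel output. All
convolutions carry weight normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import AvgPool2, Conv2d, PixelShuffle2, ReLU

__all__ = ["UNetConfig", "UNet", "IdentityOperator"]


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 3
    base_channels: int = 32
    expansion: int = 4
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.expansion < 1:
            raise ValueError("expansion must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")


class _WideBlock:
    """1×1 expansion → ReLU → k×k back to base width."""

    def __init__(self, c_in: int, base: int, expansion: int, kernel: int, rng):
        wide = base * expansion
        self.expand = Conv2d(c_in, wide, 1, rng)
        self.act = ReLU()
        self.project = Conv2d(wide, base, kernel, rng)

    def forward(self, x):
        return self.project.forward(self.act.forward(self.expand.forward(x)))

    def backward(self, dout):
        return self.expand.backward(self.act.backward(self.project.backward(dout)))

    def convs(self):
        return [self.expand, self.project]


class UNet:
    """Denoising U-net; maps (N, 1, H, W) → (N, 1, H, W), H and W divisible
    by 2**depth."""

    def __init__(self, config: UNetConfig, seed: int):
        rng = np.random.default_rng(seed)
        d, b, e, k = config.depth, config.base_channels, config.expansion, config.kernel
        self.config = config
        self.seed = seed
        self.stem = Conv2d(1, b, k, rng)
        self.enc_blocks = [_WideBlock(b, b, e, k, rng) for _ in range(d)]
        self.pools = [AvgPool2() for _ in range(d)]
        self.bottleneck = _WideBlock(b, b, e, k, rng)
        self.up_convs = [Conv2d(b, 4 * b, 1, rng) for _ in range(d)]
        self.shuffles = [PixelShuffle2() for _ in range(d)]
        self.dec_blocks = [_WideBlock(2 * b, b, e, k, rng) for _ in range(d)]
        self.head = Conv2d(b, 1, k, rng)

    # -- parameters ---------------------------------------------------------
    def _conv_layers(self) -> dict[str, Conv2d]:
        layers: dict[str, Conv2d] = {"stem": self.stem, "head": self.head}
        for i, blk in enumerate(self.enc_blocks):
            layers[f"enc{i}.expand"] = blk.expand
            layers[f"enc{i}.project"] = blk.project
        layers["bottleneck.expand"] = self.bottleneck.expand
        layers["bottleneck.project"] = self.bottleneck.project
        for i, conv in enumerate(self.up_convs):
            layers[f"up{i}"] = conv
        for i, blk in enumerate(self.dec_blocks):
            layers[f"dec{i}.expand"] = blk.expand
            layers[f"dec{i}.project"] = blk.project
        return layers

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._conv_layers().items():
            for key, arr in layer.params().items():
                out[f"{name}.{key}"] = arr
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._conv_layers().items():
            for key, arr in layer.grads.items():
                out[f"{name}.{key}"] = arr
        return out

    def set_params(self, flat: dict[str, np.ndarray]) -> None:
        for name, layer in self._conv_layers().items():
            layer.set_params(
                {key: flat[f"{name}.{key}"] for key in ("v", "g", "b")}
            )

    def n_params(self) -> int:
        return sum(int(np.prod(a.shape)) for a in self.params().values())

    def checksum(self) -> float:
        return float(sum(np.float64(a).sum() for a in self.params().values()))

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        d = self.config.depth
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W) input, got {x.shape}")
        if x.shape[2] % (1 << d) or x.shape[3] % (1 << d):
            raise ValueError(
                f"input dims {x.shape[2:]} must be divisible by 2**depth = {1 << d}"
            )
        h = self.stem.forward(x.astype(np.float32))
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        for i in range(d - 1, -1, -1):
            h = self.shuffles[i].forward(self.up_convs[i].forward(h))
            h = np.concatenate([h, skips[i]], axis=1)
            h = self.dec_blocks[i].forward(h)
        return self.head.forward(h)

    def backward(self, dout: np.ndarray) -> None:
        d = self.config.depth
        b = self.config.base_channels
        g = self.head.backward(dout)
        dskips = [None] * d
        for i in range(d):
            g = self.dec_blocks[i].backward(g)
            g, ds = g[:, :b], g[:, b:]
            dskips[i] = ds
            g = self.up_convs[i].backward(self.shuffles[i].backward(g))
        g = self.bottleneck.backward(g)
        for i in range(d - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + dskips[i]
            g = self.enc_blocks[i].backward(g)
        self.stem.backward(g)

    # -- inference ----------------------------------------------------------
    def apply(self, image: np.ndarray) -> np.ndarray:
        """Denoise a single normalized 2-D array (dims already divisible)."""
        out = self.forward(image[None, None].astype(np.float32))
        return out[0, 0]


class IdentityOperator:
    """Drop-in inference operator returning its input unchanged.

    Useful as a reference denoiser: piping it through the full inference
    pipeline reduces the pipeline to its crop/low-pass components.
    """

    config = UNetConfig(depth=1, base_channels=4, expansion=1, kernel=1)

    def apply(self, image: np.ndarray) -> np.ndarray:
        return image
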