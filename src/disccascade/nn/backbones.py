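"""Segmentation backbones: MultiResUNet and a plain U-Net.

Both share the encoder-decoder scaffold (2x2 max pool down, 2x2 stride-2
transposed convolution up, skip connections, final 1x1 convolution producing
logits).  The MultiRes block chains three 3x3 convolutions whose outputs are
concatenated and added to a 1x1 residual of the block input; with width scale
``alpha`` the three convolutions carry W/6, W/3 and W/2 filters for
W = alpha * U, U the nominal U-Net width at that level.  Skip connections
pass through Res paths: chains of 3x3 convolutions with 1x1 residuals whose
length shrinks with depth (deep skips need less reconciliation).

Tensors are NHWC internally (see ``nn.layers``); the public ``forward`` /
``backward`` accept and return NCHW to match the model contract.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvBNReLU,
    ConvTranspose2d,
    Layer,
    MaxPool2d,
    Param,
    ReLU,
)


def multires_filter_split(base_filters: int, level: int, alpha: float) -> Tuple[int, int, int]:
    """Per-convolution filter counts (W/6, W/3, W/2) at an encoder level."""
    w = alpha * base_filters * (2**level)
    return (max(1, int(w / 6)), max(1, int(w / 3)), max(1, int(w / 2)))


class MultiResBlock(Layer):
    def __init__(self, cin: int, base_filters: int, level: int, alpha: float,
                 rng: np.random.Generator):
        c1, c2, c3 = multires_filter_split(base_filters, level, alpha)
        self.filter_split = (c1, c2, c3)
        self.out_channels = c1 + c2 + c3
        self.cbr1 = ConvBNReLU(cin, c1, 3, rng)
        self.cbr2 = ConvBNReLU(c1, c2, 3, rng)
        self.cbr3 = ConvBNReLU(c2, c3, 3, rng)
        self.shortcut = Conv2d(cin, self.out_channels, 1, rng)
        self.shortcut_bn = BatchNorm2d(self.out_channels)
        self.relu = ReLU()
        self.bn_out = BatchNorm2d(self.out_channels)

    def params(self) -> List[Param]:
        return (self.cbr1.params() + self.cbr2.params() + self.cbr3.params()
                + self.shortcut.params() + self.shortcut_bn.params() + self.bn_out.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        a = self.cbr1.forward(x, train)
        b = self.cbr2.forward(a, train)
        c = self.cbr3.forward(b, train)
        cat = np.concatenate([a, b, c], axis=-1)
        s = self.shortcut_bn.forward(self.shortcut.forward(x, train), train)
        y = self.relu.forward(cat + s, train)
        return self.bn_out.forward(y, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu.backward(self.bn_out.backward(grad))
        gx = self.shortcut.backward(self.shortcut_bn.backward(g))
        c1, c2, _ = self.filter_split
        ga, gb, gc = g[..., :c1], g[..., c1 : c1 + c2], g[..., c1 + c2 :]
        gb = gb + self.cbr3.backward(gc)
        ga = ga + self.cbr2.backward(gb)
        return gx + self.cbr1.backward(ga)


class ResPath(Layer):
    """Skip-connection refinement: ``length`` residual 3x3 units."""

    def __init__(self, channels: int, length: int, rng: np.random.Generator):
        self.steps = []
        self.out_channels = channels
        self.length = max(1, length)
        for _ in range(self.length):
            self.steps.append(
                {
                    "conv3": Conv2d(channels, channels, 3, rng),
                    "bn3": BatchNorm2d(channels),
                    "conv1": Conv2d(channels, channels, 1, rng),
                    "bn1": BatchNorm2d(channels),
                    "relu": ReLU(),
                }
            )

    def params(self) -> List[Param]:
        out: List[Param] = []
        for s in self.steps:
            out += (s["conv3"].params() + s["bn3"].params()
                    + s["conv1"].params() + s["bn1"].params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for s in self.steps:
            main = s["bn3"].forward(s["conv3"].forward(x, train), train)
            res = s["bn1"].forward(s["conv1"].forward(x, train), train)
            x = s["relu"].forward(main + res, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for s in reversed(self.steps):
            g = s["relu"].backward(grad)
            grad = (s["conv3"].backward(s["bn3"].backward(g))
                    + s["conv1"].backward(s["bn1"].backward(g)))
        return grad


class UNetBlock(Layer):
    """Two chained 3x3 conv-BN-ReLU units (classic U-Net level)."""

    def __init__(self, cin: int, base_filters: int, level: int, alpha: float,
                 rng: np.random.Generator):
        cout = base_filters * (2**level)
        self.out_channels = cout
        self.cbr1 = ConvBNReLU(cin, cout, 3, rng)
        self.cbr2 = ConvBNReLU(cout, cout, 3, rng)

    def params(self) -> List[Param]:
        return self.cbr1.params() + self.cbr2.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.cbr2.forward(self.cbr1.forward(x, train), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.cbr1.backward(self.cbr2.backward(grad))


class Identity(Layer):
    out_channels: int

    def __init__(self, channels: int):
        self.out_channels = channels

    def forward(self, x, train=True):
        return x

    def backward(self, grad):
        return grad


_BLOCKS = {"multires": MultiResBlock, "unet": UNetBlock}


class EncoderDecoderNet(Layer):
    """Shared U-shaped scaffold parameterized by block type.

    ``arch='multires'`` uses MultiRes blocks + Res-path skips; ``arch='unet'``
    uses plain double-conv blocks with direct skips.  Input spatial dims must
    be divisible by ``2**depth``.  Output is a logit map with ``out_channels``
    channels at input resolution.
    """

    def __init__(self, in_channels: int, out_channels: int, base_filters: int,
                 depth: int, alpha: float, arch: str, rng: np.random.Generator,
                 max_respath_len: int = 4):
        if arch not in _BLOCKS:
            raise ValueError(f"unknown arch {arch!r}")
        block_cls = _BLOCKS[arch]
        self.depth = depth
        self.arch = arch
        self.enc_blocks: List[Layer] = []
        self.pools: List[MaxPool2d] = []
        self.skips: List[Layer] = []
        cin = in_channels
        for lvl in range(depth):
            blk = block_cls(cin, base_filters, lvl, alpha, rng)
            self.enc_blocks.append(blk)
            self.pools.append(MaxPool2d())
            if arch == "multires":
                length = min(depth - lvl, max_respath_len)
                self.skips.append(ResPath(blk.out_channels, length, rng))
            else:
                self.skips.append(Identity(blk.out_channels))
            cin = blk.out_channels
        self.bottleneck = block_cls(cin, base_filters, depth, alpha, rng)
        cin = self.bottleneck.out_channels
        self.upconvs: List[ConvTranspose2d] = []
        self.dec_blocks: List[Layer] = []
        for lvl in reversed(range(depth)):
            skip_c = self.enc_blocks[lvl].out_channels
            self.upconvs.append(ConvTranspose2d(cin, skip_c, rng))
            blk = block_cls(2 * skip_c, base_filters, lvl, alpha, rng)
            self.dec_blocks.append(blk)
            cin = blk.out_channels
        self.head = Conv2d(cin, out_channels, 1, rng)
        self.out_channels = out_channels

    def params(self) -> List[Param]:
        out: List[Param] = []
        for m in (*self.enc_blocks, *self.skips, self.bottleneck,
                  *self.upconvs, *self.dec_blocks, self.head):
            out += m.params()
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h, w = x.shape[-2:]
        if h % (2**self.depth) or w % (2**self.depth):
            raise ValueError(
                f"spatial dims {(h, w)} must be divisible by 2**depth = {2**self.depth}"
            )
        # NCHW in -> NHWC internally
        x = np.ascontiguousarray(np.transpose(x, (0, 2, 3, 1)), dtype=np.float32)
        skips = []
        for blk, pool, skip in zip(self.enc_blocks, self.pools, self.skips):
            x = blk.forward(x, train)
            skips.append(skip.forward(x, train))
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = [s.shape[-1] for s in skips]
        for up, blk, s in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            x = blk.forward(np.concatenate([s, x], axis=-1), train)
        y = self.head.forward(x, train)
        return np.ascontiguousarray(np.transpose(y, (0, 3, 1, 2)))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = np.ascontiguousarray(np.transpose(grad, (0, 2, 3, 1)), dtype=np.float32)
        grad = self.head.backward(grad)
        skip_grads = []
        for up, blk, sc in zip(reversed(self.upconvs), reversed(self.dec_blocks),
                               self._skip_channels):
            g = blk.backward(grad)
            skip_grads.append(g[..., :sc])
            grad = up.backward(np.ascontiguousarray(g[..., sc:]))
        grad = self.bottleneck.backward(grad)
        # skip_grads[i] holds the gradient for encoder level i (decoder walked
        # its steps in reverse, i.e. from level 0 upward)
        for blk, pool, skip, sg in zip(reversed(self.enc_blocks), reversed(self.pools),
                                       reversed(self.skips), reversed(skip_grads)):
            g = pool.backward(grad) + skip.backward(sg)
            grad = blk.backward(g)
        grad = np.transpose(grad, (0, 3, 1, 2))
        return grad
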