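"""U-net shared by the enhancement and segmentation networks.

Architecture: three down-blocks, each of three zero-padded 3x3
convolutions (the second doubles the channel count) followed by 2x2
average pooling; an extra convolution at the bottom; three up-blocks,
each a bilinear x2 upsample, a skip concatenation that doubles the
channels, and three convolutions (the second quarters the channels).
Leaky ReLU (slope 0.1) follows every convolution except the last, which
maps back to the output channels (RGB for enhancement, three class
logits for segmentation).  The first convolution lifts the input to
``base_channels`` (32 at full scale).  Spatial size is preserved inside
blocks, so any input whose side is divisible by ``2**depth`` is valid at
inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import AvgPool2, BilinearUp2, Conv2d, LeakyReLU


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 3
    base_channels: int = 32
    convs_per_block: int = 3
    kernel: int = 3
    leaky_slope: float = 0.1
    in_channels: int = 3
    out_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1 or self.convs_per_block < 2:
            raise ValueError("invalid UNetConfig")


@dataclass
class _TraceEntry:
    stage: str
    c_in: int
    c_out: int


class UNet:
    """Explicit-graph U-net with manual backpropagation."""

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        act = lambda: LeakyReLU(cfg.leaky_slope)  # noqa: E731
        self.trace: list[_TraceEntry] = []

        def conv(stage, c_in, c_out):
            self.trace.append(_TraceEntry(stage, c_in, c_out))
            return Conv2d(c_in, c_out, rng, cfg.kernel, name=stage)

        self.down_blocks = []
        c = cfg.in_channels
        for d in range(cfg.depth):
            block = []
            if d == 0:
                block.append(conv(f"down{d}.conv0", c, cfg.base_channels))
                c = cfg.base_channels
            else:
                block.append(conv(f"down{d}.conv0", c, c))
            block.append(conv(f"down{d}.conv1", c, 2 * c))  # doubles
            c = 2 * c
            for i in range(2, cfg.convs_per_block):
                block.append(conv(f"down{d}.conv{i}", c, c))
            self.down_blocks.append(block)
        self.pools = [AvgPool2() for _ in range(cfg.depth)]

        self.bottom = conv("bottom.conv", c, c)

        self.up_blocks = []
        self.ups = []
        for d in range(cfg.depth):
            self.ups.append(BilinearUp2())
            c_cat = 2 * c  # skip concatenation doubles
            block = [conv(f"up{d}.conv0", c_cat, c_cat),
                     conv(f"up{d}.conv1", c_cat, c_cat // 4)]  # quarters
            c = c_cat // 4
            for i in range(2, cfg.convs_per_block):
                block.append(conv(f"up{d}.conv{i}", c, c))
            self.up_blocks.append(block)

        self.final = conv("final.conv", c, cfg.out_channels)
        self._acts: dict[int, LeakyReLU] = {}
        self._act_factory = act

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        ps = []
        for block in self.down_blocks:
            for conv in block:
                ps.extend(conv.params)
        ps.extend(self.bottom.params)
        for block in self.up_blocks:
            for conv in block:
                ps.extend(conv.params)
        ps.extend(self.final.params)
        return ps

    def channel_trace(self):
        """(stage, c_in, c_out) records for architecture audits."""
        return [(t.stage, t.c_in, t.c_out) for t in self.trace]

    # -- forward / backward -------------------------------------------------
    def _act(self, key):
        if key not in self._acts:
            self._acts[key] = self._act_factory()
        return self._acts[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """NCHW batch in, NCHW batch out (same spatial size)."""
        n, c, h, w = x.shape
        div = 2 ** self.cfg.depth
        if h % div or w % div:
            raise ValueError(
                f"input side must be divisible by {div}, got {h}x{w}")
        self._skip_shapes = []
        t = x
        self._skips = []
        for d, block in enumerate(self.down_blocks):
            for i, conv in enumerate(block):
                t = self._act(("d", d, i)).forward(conv.forward(t))
            self._skips.append(t)
            t = self.pools[d].forward(t)
        t = self._act(("b",)).forward(self.bottom.forward(t))
        for d, block in enumerate(self.up_blocks):
            t = self.ups[d].forward(t)
            skip = self._skips[self.cfg.depth - 1 - d]
            t = np.concatenate([t, skip], axis=1)
            self._cat_split = t.shape[1] // 2  # same every level by schedule
            for i, conv in enumerate(block):
                t = self._act(("u", d, i)).forward(conv.forward(t))
        return self.final.forward(t)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.final.backward(gout)
        skip_grads = [None] * self.cfg.depth
        for d in reversed(range(len(self.up_blocks))):
            block = self.up_blocks[d]
            for i in reversed(range(len(block))):
                g = block[i].backward(self._act(("u", d, i)).backward(g))
            half = g.shape[1] // 2
            g_up, g_skip = g[:, :half], g[:, half:]
            skip_grads[self.cfg.depth - 1 - d] = g_skip
            g = self.ups[d].backward(g_up)
        g = self.bottom.backward(self._act(("b",)).backward(g))
        for d in reversed(range(len(self.down_blocks))):
            g = self.pools[d].backward(g)
            g = g + skip_grads[d]
            block = self.down_blocks[d]
            for i in reversed(range(len(block))):
                g = block[i].backward(self._act(("d", d, i)).backward(g))
        self._skips = []
        return g


def build_unet(cfg: UNetConfig) -> UNet:
    """Construct a U-net; the channel schedule is available via
    ``net.channel_trace()`` for programmatic auditing."""
    return UNet(cfg)
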