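"""Densely connected convolution block.

Every layer consumes the channel-concatenation of the block input and all
previous layers' outputs, and contributes ``growth`` new channels at
unchanged spatial size (pre-activation ordering: normalize -> rectify ->
convolve, 3x3 same-padded).  The block output therefore has exactly
C_in + n_layers * growth channels, and its first C_in channels are the input
passed through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm2d, Conv2d, Module
from .tensor import Tensor, concatenate

__all__ = ["DenseBlockConfig", "DenseBlock", "dense_block_forward"]


@dataclass
class DenseBlockConfig:
    n_layers: int = 8
    growth: int = 32
    kernel: int = 3

    def out_channels(self, in_channels):
        return in_channels + self.n_layers * self.growth


class DenseBlock(Module):
    def __init__(self, in_channels, cfg: DenseBlockConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.in_channels = in_channels
        self.norms = []
        self.convs = []
        c = in_channels
        for _ in range(cfg.n_layers):
            if cfg.growth > 0:
                self.norms.append(BatchNorm2d(c))
                self.convs.append(Conv2d(c, cfg.growth, cfg.kernel,
                                         stride=1, padding="same", rng=rng))
            c += cfg.growth
        self.out_channels = c

    def forward(self, x):
        if self.cfg.growth == 0:
            return x
        feats = [x]
        current = x
        for norm, conv in zip(self.norms, self.convs):
            y = conv(norm(current).relu())
            feats.append(y)
            current = concatenate(feats, axis=-1)
        return current

    __call__ = forward


def dense_block_forward(x, cfg: DenseBlockConfig, seed=0):
    """Run a freshly initialized dense block on an H x W x C (or N,H,W,C) map."""
    x = np.asarray(x, dtype=np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    rng = np.random.default_rng(seed)
    block = DenseBlock(x.shape[-1], cfg, rng).eval()
    out = block(Tensor(x)).data
    return out[0] if single else out
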