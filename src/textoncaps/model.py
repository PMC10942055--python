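"""The tri-level texton-dense capsule classifier.

Each of the three levels applies texton selection, a densely connected
convolution block, and a convolutional primary-capsule layer; the squashed
primary-capsule activations of one level (re-laid-out as a feature map) are
the input to the next.  Four class-capsule heads are routed from the three
primary-capsule sets — one per level plus one from their concatenation — and
their per-class capsules are concatenated into a single 54-dimensional
capsule per class whose Euclidean length is the class score.  A four-layer
fully connected decoder reconstructs the input from the selected class's
concatenated capsule as a regularizer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import texton as _texton
from .capsules import (ClassCapsule, MarginLossParams, PrimaryCapsule,
                       capsule_lengths, conv_output_size, lengths_t, squash_t)
from .dense_block import DenseBlock, DenseBlockConfig
from .layers import Linear, Module
from .tensor import Tensor, concatenate

__all__ = ["ModelConfig", "ForwardOutput", "TTDCapsNet", "build", "forward",
           "predict", "count_parameters"]


@dataclass
class ModelConfig:
    """Every architectural hyperparameter of the network."""

    height: int = 32
    width: int = 32
    channels: int = 3
    n_classes: int = 4
    # primary capsules: 12 types of 8-D capsules, unpadded convs
    pc_types: int = 12
    pc_dim: int = 8
    pc_kernels: tuple = (5, 5, 3)
    pc_strides: tuple = (2, 2, 2)
    # class-capsule heads: [combined, level1, level2, level3]
    head_dims: tuple = (16, 16, 12, 10)
    # dense blocks
    dense_layers: int = 8
    growth: int = 32
    dense_kernel: int = 3
    # routing
    routing_iters: int = 3
    routing_update: str = "inloop"
    # texton layers
    texton_step: int = 1
    texton_levels: int = 256
    texton_types: int = 6
    # decoder hidden widths; final width is height*width*channels
    decoder_hidden: tuple = (512, 512, 1024)
    # loss
    loss: MarginLossParams = field(default_factory=MarginLossParams)
    recon_weight: float = 0.0005

    def __post_init__(self):
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 (grayscale) or 3 (RGB)")
        if len(self.pc_kernels) != 3 or len(self.pc_strides) != 3:
            raise ValueError("three primary-capsule levels are required")
        if len(self.head_dims) != 4:
            raise ValueError("four class-capsule heads are required")
        if self.texton_types not in (4, 6):
            raise ValueError("texton_types must be 4 or 6")

    @property
    def concat_dim(self):
        return int(sum(self.head_dims))

    @property
    def input_size(self):
        return self.height * self.width * self.channels

    @classmethod
    def compact(cls, n_classes=4, channels=3):
        """Desk-scale configuration trainable in minutes on one CPU core."""
        return cls(n_classes=n_classes, channels=channels,
                   pc_types=4, dense_layers=2, growth=8,
                   texton_levels=32, decoder_hidden=(128, 128, 256))

    def to_dict(self):
        d = asdict(self)
        d["pc_kernels"] = list(self.pc_kernels)
        d["pc_strides"] = list(self.pc_strides)
        d["head_dims"] = list(self.head_dims)
        d["decoder_hidden"] = list(self.decoder_hidden)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        loss = d.pop("loss", {})
        return cls(loss=MarginLossParams(**loss) if isinstance(loss, dict) else loss,
                   **{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


@dataclass
class ForwardOutput:
    """Everything one forward pass produces."""

    head_caps: list          # four (B, n_classes, head_dim) arrays
    head_lengths: list       # four (B, n_classes) arrays
    concat_caps: np.ndarray  # (B, n_classes, 54)
    reconstruction: np.ndarray  # (B, H*W*C)
    # live autodiff tensors, present when the pass was run for training
    head_length_tensors: list = None
    reconstruction_tensor: Tensor = None


class TTDCapsNet(Module):
    """Three texton-dense levels, four routed class-capsule heads, a decoder."""

    def __init__(self, cfg: ModelConfig, seed=0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        tset = _texton.ALL_TEXTONS[:cfg.texton_types]
        dense_cfg = DenseBlockConfig(cfg.dense_layers, cfg.growth, cfg.dense_kernel)

        self.textons = [ _texton.TextonLayer(levels=cfg.texton_levels,
                                             step=cfg.texton_step, texton_set=tset)
                         for _ in range(3) ]

        pc_channels = cfg.pc_types * cfg.pc_dim
        self.blocks, self.pcs = [], []
        self.grid_sizes = []  # (H, W) of each primary-capsule grid
        h, w, c = cfg.height, cfg.width, cfg.channels
        for k, s in zip(cfg.pc_kernels, cfg.pc_strides):
            block = DenseBlock(c, dense_cfg, rng)
            if k > min(h, w):
                raise ValueError(f"primary-capsule kernel {k} exceeds input {h}x{w}")
            self.blocks.append(block)
            self.pcs.append(PrimaryCapsule(block.out_channels, cfg.pc_types,
                                           cfg.pc_dim, k, s, rng))
            h, w = conv_output_size(h, k, s), conv_output_size(w, k, s)
            self.grid_sizes.append((h, w))
            c = pc_channels
        self.pc_counts = [gh * gw * cfg.pc_types for gh, gw in self.grid_sizes]

        n_combined = sum(self.pc_counts)
        head_sources = [n_combined] + self.pc_counts
        self.heads = [ClassCapsule(n_in, cfg.pc_dim, cfg.n_classes, dim, rng,
                                   r=cfg.routing_iters, update=cfg.routing_update)
                      for n_in, dim in zip(head_sources, cfg.head_dims)]

        d1, d2, d3 = cfg.decoder_hidden
        self.dec1 = Linear(cfg.concat_dim, d1, rng)
        self.dec2 = Linear(d1, d2, rng)
        self.dec3 = Linear(d1 + d2, d3, rng)
        self.dec4 = Linear(d3, cfg.input_size, rng)

    # ------------------------------------------------------------------
    def _validate_batch(self, batch):
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 3:
            batch = batch[None]
        expected = (self.cfg.height, self.cfg.width, self.cfg.channels)
        if batch.shape[1:] != expected:
            raise ValueError(f"batch shape {batch.shape[1:]} != expected {expected}")
        if batch.min() < 0 or batch.max() > 1:
            raise ValueError("batch values must lie in [0, 1]")
        return batch

    def forward(self, batch, mask_labels=None, need_tensors=False):
        """Full forward pass.

        mask_labels (one-hot, training) selects whose class capsule feeds the
        decoder; without it the argmax class is decoded.
        """
        batch = self._validate_batch(batch)
        x = Tensor(batch)
        pc_caps = []
        for tex, block, pc in zip(self.textons, self.blocks, self.pcs):
            x = tex(x)
            x = block(x)
            caps, x = pc(x)
            pc_caps.append(caps)

        combined = concatenate(pc_caps, axis=1)
        sources = [combined] + pc_caps
        head_vs, head_len_ts = [], []
        for head, src in zip(self.heads, sources):
            v, _ = head(src)
            head_vs.append(v)
            head_len_ts.append(lengths_t(v))

        concat = concatenate(head_vs, axis=-1)  # (B, n_classes, 54)

        if mask_labels is not None:
            onehot = np.asarray(mask_labels, dtype=np.float32)
            if onehot.ndim == 1:
                onehot = np.eye(self.cfg.n_classes, dtype=np.float32)[
                    onehot.astype(int)]
        else:
            scores = capsule_lengths(concat.data)
            onehot = np.eye(self.cfg.n_classes, dtype=np.float32)[
                scores.argmax(axis=1)]
        selected = (concat * Tensor(onehot[..., None])).sum(axis=1)  # (B, 54)

        h1 = self.dec1(selected).relu()
        h2 = self.dec2(h1).relu()
        h3 = self.dec3(concatenate([h1, h2], axis=-1)).relu()
        recon = self.dec4(h3).sigmoid()

        return ForwardOutput(
            head_caps=[v.data for v in head_vs],
            head_lengths=[t.data for t in head_len_ts],
            concat_caps=concat.data,
            reconstruction=recon.data,
            head_length_tensors=head_len_ts if need_tensors else None,
            reconstruction_tensor=recon if need_tensors else None,
        )

    __call__ = forward

    def predict(self, batch):
        """Labels and per-class scores (lengths of the concatenated capsules).

        Ties break toward the lowest class index (numpy argmax convention).
        """
        out = self.forward(batch)
        scores = capsule_lengths(out.concat_caps)
        return scores.argmax(axis=1), scores

    def count_parameters(self):
        """Total trainable scalars and a per-component breakdown."""
        breakdown = {}
        for i, (block, pc) in enumerate(zip(self.blocks, self.pcs), start=1):
            breakdown[f"dense_block_{i}"] = block.n_parameters()
            breakdown[f"primary_capsule_{i}"] = pc.n_parameters()
        for i, head in enumerate(self.heads):
            breakdown[f"class_capsule_head_{i}"] = head.n_parameters()
        breakdown["decoder"] = sum(m.n_parameters()
                                   for m in (self.dec1, self.dec2, self.dec3, self.dec4))
        return self.n_parameters(), breakdown

    # -- checkpointing ---------------------------------------------------
    def save(self, path):
        state = self.state_dict()
        np.savez(path, __config__=json.dumps(self.cfg.to_dict()), **state)

    @classmethod
    def load(cls, path, seed=0):
        with np.load(path, allow_pickle=False) as data:
            cfg = ModelConfig.from_dict(json.loads(str(data["__config__"])))
            model = cls(cfg, seed=seed)
            model.load_state_dict({k: data[k] for k in data.files
                                   if k != "__config__"})
        return model.eval()


# thin functional wrappers -------------------------------------------------

def build(cfg: ModelConfig, seed=0) -> TTDCapsNet:
    return TTDCapsNet(cfg, seed=seed)


def forward(model: TTDCapsNet, batch, mask_labels=None) -> ForwardOutput:
    return model.forward(batch, mask_labels=mask_labels)


def predict(model: TTDCapsNet, batch):
    return model.predict(batch)


def count_parameters(model: TTDCapsNet):
    return model.count_parameters()
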