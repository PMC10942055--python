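"""Neural building blocks (modules) and the Adam optimizer.

Modules hold :class:`~textoncaps.tensor.Tensor` parameters and expose
``train()`` / ``eval()`` modes; convolution is im2col + matmul so the heavy
lifting stays inside BLAS.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, im2col, matmul, pad2d


class Module:
    """Base class: parameter discovery by attribute walk, train/eval modes."""

    def __init__(self):
        self.training = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for mod in (self, *self.modules()):
            for value in mod.__dict__.values():
                if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
                    seen.add(id(value))
                    yield value

    def named_parameters(self, prefix=""):
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{path}.{i}.")

    def n_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    # serialization: flat dict of numpy arrays keyed by parameter path
    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix=""):
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_buffers(prefix=path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{path}.{i}.")

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = value.astype(np.float32)
            elif key in buffers:
                buffers[key][...] = value
            else:
                raise KeyError(f"unknown state entry {key}")


class Linear(Module):
    def __init__(self, in_features, out_features, rng, init="he"):
        super().__init__()
        if init == "he":
            scale = np.sqrt(2.0 / in_features)
        else:
            scale = float(init)
        self.weight = Tensor(rng.normal(0.0, scale, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x):
        return matmul(x, self.weight) + self.bias

    __call__ = forward


class Conv2d(Module):
    """2-D convolution on NHWC tensors. padding: 'valid' or 'same' (stride 1)."""

    def __init__(self, in_channels, out_channels, kernel, stride=1, padding="valid",
                 rng=None, bias=True):
        super().__init__()
        kh = kw = int(kernel)
        self.kernel = (kh, kw)
        self.stride = (int(stride), int(stride))
        self.padding = padding
        fan_in = in_channels * kh * kw
        scale = np.sqrt(2.0 / fan_in)
        # stored flat in the same (C, kh, kw) order im2col emits
        self.weight = Tensor(rng.normal(0.0, scale, (fan_in, out_channels)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x):
        if x.data.shape[-1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.data.shape[-1]}")
        if self.padding == "same":
            ph = (self.kernel[0] - 1) // 2
            pw = (self.kernel[1] - 1) // 2
            x = pad2d(x, ph, pw)
        cols = im2col(x, self.kernel, self.stride)  # (N, OH, OW, C*kh*kw)
        out = matmul(cols, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out

    __call__ = forward


class BatchNorm2d(Module):
    """Per-channel normalization over (N, H, W) of an NHWC tensor."""

    def __init__(self, channels, eps=1e-5, momentum=0.9):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 1, 2), keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.reshape(-1)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean.reshape(1, 1, 1, -1))
            var = Tensor(self.running_var.reshape(1, 1, 1, -1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma + self.beta

    __call__ = forward


class Adam:
    """Adaptive-moment gradient descent (the optimizer used for training)."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
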