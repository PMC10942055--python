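"""Capsule primitives: squash, votes, dynamic routing-by-agreement, margin loss.

A capsule is a vector-valued unit whose length encodes the probability that
an entity is present and whose direction encodes its pose.  Lower capsules
send votes (linear transforms of their activity vectors) to upper capsules;
routing-by-agreement iteratively concentrates each lower capsule's coupling
coefficients on the upper capsules its vote agrees with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Module
from .tensor import Tensor, matmul, softmax

__all__ = [
    "squash",
    "compute_votes",
    "dynamic_routing",
    "margin_loss",
    "RoutingState",
    "MarginLossParams",
    "PrimaryCapsule",
    "ClassCapsule",
]

_SQUASH_EPS = 1e-9


# ---------------------------------------------------------------------------
# functional API (plain numpy in / numpy out)
# ---------------------------------------------------------------------------

def squash(s, axis=-1):
    """v = (|s|^2 / (1 + |s|^2)) * s / |s|, with squash(0) = 0.

    Bounds every capsule length to [0, 1) while preserving direction; a small
    additive stabilizer inside the norm makes the zero vector well defined.
    """
    s = np.asarray(s, dtype=np.float64)
    if not np.isfinite(s).all():
        raise ValueError("squash requires finite input")
    n2 = (s * s).sum(axis=axis, keepdims=True)
    scale = n2 / (1.0 + n2) / np.sqrt(n2 + _SQUASH_EPS)
    return s * scale


def squash_t(s: Tensor, axis=-1) -> Tensor:
    """Autodiff version of :func:`squash` for in-network use."""
    n2 = (s * s).sum(axis=axis, keepdims=True)
    scale = (n2 / (n2 + 1.0)) / ((n2 + _SQUASH_EPS) ** 0.5)
    return s * scale


def compute_votes(u, weights):
    """Votes û_{j|i} = W_ij u_i.

    u: (N, D_in) or (B, N, D_in); weights: (N, J, D_in, D_out).
    Returns (N, J, D_out) or (B, N, J, D_out).
    """
    u = np.asarray(u, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if u.shape[-1] != weights.shape[2]:
        raise ValueError(
            f"capsule dimension mismatch: u has D_in={u.shape[-1]}, "
            f"weights expect D_in={weights.shape[2]}")
    if u.shape[-2] != weights.shape[0]:
        raise ValueError(
            f"capsule count mismatch: u has N={u.shape[-2]}, "
            f"weights expect N={weights.shape[0]}")
    return np.einsum("...ni,njio->...njo", u, weights)


@dataclass
class RoutingState:
    """Routing by-products: final logits b_ij and the couplings that built v."""

    logits: np.ndarray
    couplings: np.ndarray
    iterations: int
    coupling_history: list = field(default_factory=list)


def dynamic_routing(votes, r=3, update="inloop"):
    """Dynamic routing-by-agreement over votes (..., N, J, D).

    Per iteration: c_i = softmax(b_i) over upper capsules, s_j = sum_i c_ij
    û_{j|i}, v_j = squash(s_j), then b_ij += v_j . û_{j|i}.  ``update='inloop'``
    applies the agreement update inside each of the r iterations (the
    conventional form); ``update='after'`` recomputes c from the initial zero
    logits every iteration and applies the b-update once, after the loop (the
    routing procedure exactly as printed).
    """
    if r < 1:
        raise ValueError("routing requires r >= 1")
    if update not in ("inloop", "after"):
        raise ValueError("update must be 'inloop' or 'after'")
    votes = np.asarray(votes, dtype=np.float64)
    b = np.zeros(votes.shape[:-1])
    history = []
    for _ in range(r):
        e = np.exp(b - b.max(axis=-1, keepdims=True))
        c = e / e.sum(axis=-1, keepdims=True)
        history.append(c.copy())
        s = (c[..., None] * votes).sum(axis=-3)
        v = squash(s)
        agreement = (v[..., None, :, :] * votes).sum(axis=-1)
        if update == "inloop":
            b = b + agreement
    if update == "after":
        b = b + agreement
    return v, RoutingState(logits=b, couplings=c, iterations=r,
                           coupling_history=history)


def _routing_t(votes: Tensor, r=3, update="inloop"):
    """Autodiff routing on a (B, N, J, D) vote tensor; gradients flow through
    every iteration."""
    if r < 1:
        raise ValueError("routing requires r >= 1")
    b = Tensor(np.zeros(votes.data.shape[:-1], dtype=np.float32))
    for _ in range(r):
        c = softmax(b, axis=-1)
        s = (c.reshape(*c.data.shape, 1) * votes).sum(axis=1)
        v = squash_t(s)
        agreement = (v.reshape(v.data.shape[0], 1, *v.data.shape[1:]) * votes).sum(axis=-1)
        if update == "inloop":
            b = b + agreement
    if update == "after":
        b = b + agreement
    return v, RoutingState(logits=b.data, couplings=c.data, iterations=r)


@dataclass
class MarginLossParams:
    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5

    def __post_init__(self):
        if not (0 < self.m_minus < self.m_plus <= 1):
            raise ValueError("need 0 < m_minus < m_plus <= 1")
        if self.lam <= 0:
            raise ValueError("lam must be positive")


def _check_one_hot(targets):
    targets = np.asarray(targets)
    if targets.ndim == 1:
        targets = targets[None, :]
    ok = np.all(np.isin(targets, (0, 1))) and np.all(targets.sum(axis=-1) == 1)
    if not ok:
        raise ValueError("targets must be one-hot")
    return targets


def margin_loss(lengths, targets, params: MarginLossParams = MarginLossParams()):
    """Per-class hinge-squared loss on capsule lengths.

    L = sum_k [ T_k max(0, m+ - |v_k|)^2 + lam (1 - T_k) max(0, |v_k| - m-)^2 ]
    averaged over the batch.
    """
    lengths = np.asarray(lengths, dtype=np.float64)
    if lengths.ndim == 1:
        lengths = lengths[None, :]
    targets = _check_one_hot(targets)
    pos = np.maximum(0.0, params.m_plus - lengths) ** 2
    neg = np.maximum(0.0, lengths - params.m_minus) ** 2
    per_sample = (targets * pos + params.lam * (1 - targets) * neg).sum(axis=-1)
    return float(per_sample.mean())


def margin_loss_t(lengths: Tensor, targets, params: MarginLossParams) -> Tensor:
    targets = _check_one_hot(targets).astype(np.float32)
    pos = (Tensor(np.float32(params.m_plus)) - lengths).relu() ** 2
    neg = (lengths - Tensor(np.float32(params.m_minus))).relu() ** 2
    per_sample = (Tensor(targets) * pos + params.lam * (Tensor(1.0 - targets)) * neg).sum(axis=-1)
    return per_sample.mean()


# ---------------------------------------------------------------------------
# capsule layers (modules)
# ---------------------------------------------------------------------------

def conv_output_size(size, kernel, stride):
    return (size - kernel) // stride + 1


class PrimaryCapsule(Module):
    """Convolutional capsule layer.

    One unpadded convolution producing n_types*dim channels, reshaped to a
    grid of n_types capsule types per cell with `dim` components each, then
    squashed per capsule.  Returns both the flat capsule tensor and the
    squashed activations re-laid-out as a feature map (which feeds the next
    network level).
    """

    def __init__(self, in_channels, n_types, dim, kernel, stride, rng):
        super().__init__()
        from .layers import Conv2d
        self.n_types = n_types
        self.dim = dim
        self.conv = Conv2d(in_channels, n_types * dim, kernel, stride=stride,
                           padding="valid", rng=rng)

    def forward(self, x):
        out = self.conv(x)  # (B, H', W', n_types*dim)
        B, H, W, _ = out.data.shape
        caps = out.reshape(B, H * W * self.n_types, self.dim)
        caps = squash_t(caps)
        fmap = caps.reshape(B, H, W, self.n_types * self.dim)
        return caps, fmap

    __call__ = forward


class ClassCapsule(Module):
    """Fully connected capsule layer: votes + dynamic routing to J classes."""

    def __init__(self, n_in, in_dim, n_classes, out_dim, rng, r=3,
                 update="inloop", init_sigma=0.01):
        super().__init__()
        self.n_in, self.in_dim = n_in, in_dim
        self.n_classes, self.out_dim = n_classes, out_dim
        self.r = r
        self.update = update
        self.weight = Tensor(
            rng.normal(0.0, init_sigma, (n_in, n_classes, in_dim, out_dim)),
            requires_grad=True)

    def votes(self, u: Tensor) -> Tensor:
        B = u.data.shape[0]
        uu = u.reshape(B, self.n_in, 1, 1, self.in_dim)
        W = self.weight.reshape(1, self.n_in, self.n_classes, self.in_dim, self.out_dim)
        return matmul(uu, W).reshape(B, self.n_in, self.n_classes, self.out_dim)

    def forward(self, u: Tensor):
        if u.data.shape[-1] != self.in_dim or u.data.shape[-2] != self.n_in:
            raise ValueError(
                f"expected ({self.n_in}, {self.in_dim}) capsules, "
                f"got {u.data.shape[-2:]}")
        v, state = _routing_t(self.votes(u), r=self.r, update=self.update)
        return v, state

    __call__ = forward


def class_capsule_forward(caps, n_classes, out_dim, r, weights):
    """Functional class-capsule layer on plain arrays (compute votes + route)."""
    votes = compute_votes(caps, weights)
    if weights.shape[1] != n_classes or weights.shape[3] != out_dim:
        raise ValueError("weights inconsistent with n_classes/out_dim")
    return dynamic_routing(votes, r=r)


def capsule_lengths(v, axis=-1):
    v = np.asarray(v, dtype=np.float64)
    return np.sqrt((v * v).sum(axis=axis))


def lengths_t(v: Tensor, axis=-1) -> Tensor:
    return ((v * v).sum(axis=axis) + _SQUASH_EPS) ** 0.5
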