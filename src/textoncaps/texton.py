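"""Multi-texton detection on 2x2 pixel grids.

A texton here is a 2x2 neighbourhood in which a designated pair of pixels
share the same value.  Six pair geometries are tested in a fixed order
(horizontal top, anti-diagonal, vertical left, main diagonal, vertical
right, horizontal bottom).  Scanning an image with this detector and zeroing
every pixel not covered by a detected grid yields the *texton image* used as
the feature-selection front end of each network level.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .layers import Module
from .tensor import Tensor

__all__ = [
    "TextonType",
    "TextonImage",
    "classify_grid",
    "detect_textons",
    "apply_texton_layer",
    "TextonLayer",
]

# corners of the 2x2 grid: V1=top-left, V2=top-right, V3=bottom-left, V4=bottom-right
_V1, _V2, _V3, _V4 = (0, 0), (0, 1), (1, 0), (1, 1)


class TextonType(enum.Enum):
    T1 = 1  # horizontal top        (V1, V2)
    T2 = 2  # anti-diagonal         (V2, V3)
    T3 = 3  # vertical left         (V1, V3)
    T4 = 4  # main diagonal         (V1, V4)
    T5 = 5  # vertical right        (V2, V4)
    T6 = 6  # horizontal bottom     (V3, V4)

    @property
    def pair(self):
        return _PAIRS[self]


_PAIRS = {
    TextonType.T1: (_V1, _V2),
    TextonType.T2: (_V2, _V3),
    TextonType.T3: (_V1, _V3),
    TextonType.T4: (_V1, _V4),
    TextonType.T5: (_V2, _V4),
    TextonType.T6: (_V3, _V4),
}

ALL_TEXTONS = tuple(TextonType)
FOUR_TEXTONS = tuple(TextonType)[:4]


@dataclass
class TextonImage:
    """A texton-filtered image: original values where detected, zero elsewhere."""

    values: np.ndarray
    mask: np.ndarray
    step: int = 1

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have the same shape")

    @property
    def coverage(self):
        return float(self.mask.mean()) if self.mask.size else 0.0


def classify_grid(v1, v2, v3, v4, texton_set=ALL_TEXTONS):
    """Classify one 2x2 grid; returns the first matching texton type or None.

    The pair tests run in the fixed order T1..T6, so detection is mutually
    exclusive per grid.
    """
    corners = {_V1: v1, _V2: v2, _V3: v3, _V4: v4}
    members = set(texton_set)
    for t in ALL_TEXTONS:
        if t not in members:
            continue
        a, b = t.pair
        if corners[a] == corners[b]:
            return t
    return None


def _pair_equal_maps(img, tol):
    """Equality maps for all six pairs, at every anchor of an (..., H, W) array."""
    v1 = img[..., :-1, :-1]
    v2 = img[..., :-1, 1:]
    v3 = img[..., 1:, :-1]
    v4 = img[..., 1:, 1:]
    corners = {_V1: v1, _V2: v2, _V3: v3, _V4: v4}

    def eq(a, b):
        if tol == 0:
            return a == b
        return np.abs(a.astype(np.float64) - b.astype(np.float64)) <= tol

    return {t: eq(corners[t.pair[0]], corners[t.pair[1]]) for t in ALL_TEXTONS}


def _anchor_grid(shape, step):
    """Boolean map of valid anchors (top-left corners) under the scan step."""
    H, W = shape[-2], shape[-1]
    sel = np.zeros((H, W), dtype=bool)
    sel[0:H:step, 0:W:step] = True
    return sel


def _scatter_grid(mask, fired):
    """OR a fired-anchor map onto all four corners of each anchored grid."""
    mask[..., :-1, :-1] |= fired
    mask[..., :-1, 1:] |= fired
    mask[..., 1:, :-1] |= fired
    mask[..., 1:, 1:] |= fired


def texton_mask(img, step=1, texton_set=ALL_TEXTONS, tol=0, keep="grid"):
    """Boolean detection mask for an (..., H, W) integer (or tolerant) image.

    keep='grid' retains the whole 2x2 grid on a hit; keep='pair' retains only
    the two pixels of the first matching texton.
    """
    img = np.asarray(img)
    if step not in (1, 2):
        raise ValueError("step must be 1 or 2")
    H, W = img.shape[-2], img.shape[-1]
    mask = np.zeros(img.shape, dtype=bool)
    if H < 2 or W < 2:
        warnings.warn("image smaller than 2x2: no textons can be detected",
                      stacklevel=2)
        return mask
    eqs = _pair_equal_maps(img, tol)
    anchors = _anchor_grid(img.shape, step)[:H - 1, :W - 1]
    members = [t for t in ALL_TEXTONS if t in set(texton_set)]
    if keep == "grid":
        fired = np.zeros(eqs[ALL_TEXTONS[0]].shape, dtype=bool)
        for t in members:
            fired |= eqs[t]
        fired &= anchors
        _scatter_grid(mask, fired)
    elif keep == "pair":
        taken = np.zeros(eqs[ALL_TEXTONS[0]].shape, dtype=bool)
        for t in members:
            first = eqs[t] & ~taken & anchors
            taken |= eqs[t] & anchors
            (r1, c1), (r2, c2) = t.pair
            mask[..., r1:r1 + H - 1, c1:c1 + W - 1] |= first
            mask[..., r2:r2 + H - 1, c2:c2 + W - 1] |= first
    else:
        raise ValueError("keep must be 'grid' or 'pair'")
    return mask


def detect_textons(image, step=1, texton_set=ALL_TEXTONS, keep="grid"):
    """Scan a 2-D integer image and zero every pixel not covered by a texton.

    2x2 windows are anchored at positions advancing by ``step`` along both
    axes (anchors clamped so the window stays in bounds); masks of
    overlapping detected grids combine by logical OR.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("detect_textons expects a 2-D image")
    mask = texton_mask(image, step=step, texton_set=texton_set, keep=keep)
    values = np.where(mask, image, 0)
    return TextonImage(values=values, mask=mask, step=step)


def texton_hit_counts(image, step=1, texton_set=ALL_TEXTONS):
    """Number of anchored grids each texton type fires on (first-match order)."""
    image = np.asarray(image)
    counts = {t: 0 for t in ALL_TEXTONS}
    H, W = image.shape
    if H < 2 or W < 2:
        return counts
    members = set(texton_set)
    for i in range(0, H - 1, step):
        for j in range(0, W - 1, step):
            t = classify_grid(image[i, j], image[i, j + 1],
                              image[i + 1, j], image[i + 1, j + 1],
                              texton_set=members)
            if t is not None:
                counts[t] += 1
    return counts


def quantize_channel(channel, levels):
    """Uniform min-max quantization of one real-valued channel to integer bins.

    A constant channel maps everywhere to bin 0.
    """
    channel = np.asarray(channel, dtype=np.float64)
    lo, hi = channel.min(), channel.max()
    if hi <= lo:
        return np.zeros(channel.shape, dtype=np.int64)
    q = np.floor((channel - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def apply_texton_layer(fmap, levels=256, step=1, texton_set=ALL_TEXTONS, tol=None):
    """Texton-filter a real-valued H x W x C feature map.

    Each channel is independently quantized to ``levels`` uniform bins over
    its own min-max range, the texton detector runs on the quantized grid,
    and the resulting boolean mask multiplies the ORIGINAL real values.  If
    ``tol`` is given, quantization is skipped and pixel equality is replaced
    by |a - b| <= tol on the raw values.
    """
    fmap = np.asarray(fmap, dtype=np.float32)
    if fmap.ndim == 2:
        fmap = fmap[:, :, None]
        squeeze = True
    else:
        squeeze = False
    if levels < 2:
        raise ValueError("levels must be >= 2")
    bad = ~np.isfinite(fmap)
    if bad.any():
        ch = int(np.argwhere(bad)[0][2])
        raise ValueError(f"non-finite values in channel {ch}")
    out = np.empty_like(fmap)
    for c in range(fmap.shape[2]):
        channel = fmap[:, :, c]
        if tol is None:
            grid = quantize_channel(channel, levels)
            mask = texton_mask(grid, step=step, texton_set=texton_set)
        else:
            mask = texton_mask(channel, step=step, texton_set=texton_set, tol=tol)
        out[:, :, c] = channel * mask
    return out[:, :, 0] if squeeze else out


class TextonLayer(Module):
    """In-network texton selection on NHWC activations.

    The detection mask is computed from the forward values and treated as a
    constant of the pass (straight-through): downstream gradients are exactly
    zero at masked-out positions.
    """

    def __init__(self, levels=256, step=1, texton_set=ALL_TEXTONS, tol=None):
        super().__init__()
        self.levels = levels
        self.step = step
        self.texton_set = tuple(texton_set)
        self.tol = tol

    def forward(self, x):
        arr = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float32)
        if not np.isfinite(arr).all():
            raise ValueError("non-finite activations entering texton layer")
        # (N, C, H, W) view so each sample/channel quantizes over its own range
        chans = np.ascontiguousarray(arr.transpose(0, 3, 1, 2)).astype(np.float64)
        if self.tol is None:
            lo = chans.min(axis=(2, 3), keepdims=True)
            hi = chans.max(axis=(2, 3), keepdims=True)
            span = np.where(hi > lo, hi - lo, 1.0)
            grids = np.clip(np.floor((chans - lo) / span * self.levels),
                            0, self.levels - 1).astype(np.int64)
            mask = texton_mask(grids, step=self.step, texton_set=self.texton_set)
        else:
            mask = texton_mask(chans, step=self.step, texton_set=self.texton_set,
                               tol=self.tol)
        mask = mask.transpose(0, 2, 3, 1).astype(np.float32)
        if isinstance(x, Tensor):
            return x * Tensor(mask)
        return arr * mask

    __call__ = forward
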