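"""Dataset plumbing: IDX and image-folder readers, the stratified 80:20
split, random shift/rotation augmentation, and the synthetic textured-image
generator that makes the whole pipeline testable offline.

Images are stored as 8-bit arrays (n, H, W, C) at rest and rescaled to the
unit interval when fed to the model.
"""

from __future__ import annotations

import os
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageDataset",
    "load_idx",
    "save_idx",
    "load_image_folder",
    "split_80_20",
    "random_transform",
    "synth_textured_dataset",
]

_IDX_IMAGE_MAGIC = 0x00000803
_IDX_LABEL_MAGIC = 0x00000801


@dataclass
class ImageDataset:
    images: np.ndarray          # (n, H, W, C) uint8
    labels: np.ndarray          # (n,) int
    class_names: list = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim == 3:
            self.images = self.images[..., None]
        if self.images.ndim != 4:
            raise ValueError("images must be (n, H, W, C)")
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"count mismatch: {len(self.images)} images vs "
                f"{len(self.labels)} labels")
        if self.images.dtype != np.uint8:
            if self.images.min() < 0 or self.images.max() > 255:
                raise ValueError("at-rest pixel values must lie in [0, 255]")
            self.images = self.images.astype(np.uint8)
        if not self.class_names:
            self.class_names = [str(i) for i in range(self.n_classes)]
        if len(self.labels) and (self.labels.min() < 0
                                 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels out of range")

    def __len__(self):
        return len(self.images)

    @property
    def n_classes(self):
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def to_float(self):
        """Unit-interval float32 view for the model."""
        return self.images.astype(np.float32) / 255.0

    def subset(self, idx):
        return ImageDataset(self.images[idx], self.labels[idx],
                            class_names=list(self.class_names))


# ---------------------------------------------------------------------------
# IDX (big-endian binary layout used by the MNIST-family distributions)
# ---------------------------------------------------------------------------

def load_idx(image_file, label_file):
    with open(image_file, "rb") as f:
        header = f.read(16)
        if len(header) < 16:
            raise ValueError("truncated IDX image header")
        magic, n, rows, cols = struct.unpack(">IIII", header)
        if magic != _IDX_IMAGE_MAGIC:
            raise ValueError(f"bad IDX image magic 0x{magic:08x}")
        payload = f.read()
    if len(payload) < n * rows * cols:
        raise ValueError("truncated IDX image payload")
    images = np.frombuffer(payload, dtype=np.uint8,
                           count=n * rows * cols).reshape(n, rows, cols)
    with open(label_file, "rb") as f:
        header = f.read(8)
        if len(header) < 8:
            raise ValueError("truncated IDX label header")
        magic, n_labels = struct.unpack(">II", header)
        if magic != _IDX_LABEL_MAGIC:
            raise ValueError(f"bad IDX label magic 0x{magic:08x}")
        raw = f.read()
    if len(raw) < n_labels:
        raise ValueError("truncated IDX label payload")
    labels = np.frombuffer(raw, dtype=np.uint8, count=n_labels)
    if n != n_labels:
        raise ValueError(f"count mismatch: {n} images vs {n_labels} labels")
    return ImageDataset(images.copy(), labels.astype(int))


def save_idx(images, labels, image_file, label_file):
    """Write grayscale images/labels in IDX layout (fixture/export writer)."""
    images = np.asarray(images, dtype=np.uint8)
    if images.ndim == 4:
        if images.shape[-1] != 1:
            raise ValueError("IDX stores single-channel images")
        images = images[..., 0]
    labels = np.asarray(labels, dtype=np.uint8)
    n, rows, cols = images.shape
    with open(image_file, "wb") as f:
        f.write(struct.pack(">IIII", _IDX_IMAGE_MAGIC, n, rows, cols))
        f.write(images.tobytes())
    with open(label_file, "wb") as f:
        f.write(struct.pack(">II", _IDX_LABEL_MAGIC, len(labels)))
        f.write(labels.tobytes())


# ---------------------------------------------------------------------------
# class-per-subdirectory image folders
# ---------------------------------------------------------------------------

def load_image_folder(root, size=(32, 32), channels=3):
    """Load a directory tree with one subdirectory per class.

    Class index follows the sorted subdirectory order; every image is resized
    with bilinear interpolation.  Undecodable files are skipped with a
    warning.
    """
    from PIL import Image, UnidentifiedImageError

    subdirs = sorted(d for d in os.listdir(root)
                     if os.path.isdir(os.path.join(root, d)))
    if not subdirs:
        raise ValueError(f"no class subdirectories under {root}")
    images, labels, skipped = [], [], 0
    for k, sub in enumerate(subdirs):
        subpath = os.path.join(root, sub)
        for fname in sorted(os.listdir(subpath)):
            path = os.path.join(subpath, fname)
            if not os.path.isfile(path):
                continue
            try:
                with Image.open(path) as im:
                    im = im.convert("RGB" if channels == 3 else "L")
                    im = im.resize(size, Image.BILINEAR)
                    arr = np.asarray(im, dtype=np.uint8)
            except (UnidentifiedImageError, OSError):
                skipped += 1
                warnings.warn(f"skipping undecodable file {path}", stacklevel=2)
                continue
            if arr.ndim == 2:
                arr = arr[..., None]
            images.append(arr)
            labels.append(k)
    if not images:
        raise ValueError(f"no decodable images under {root}")
    ds = ImageDataset(np.stack(images), np.array(labels), class_names=subdirs)
    ds.skipped = skipped
    return ds


# ---------------------------------------------------------------------------
# split and augmentation
# ---------------------------------------------------------------------------

def split_80_20(ds: ImageDataset, seed=0, val_frac=0.2):
    """Stratified hold-out split: per class, floor(val_frac * count) samples
    (at least 1) go to validation, the remainder to training.  Deterministic
    under the seed; the two index sets partition the dataset."""
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for k in range(ds.n_classes):
        idx = np.flatnonzero(ds.labels == k)
        if len(idx) < 2:
            raise ValueError(f"class {k} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_val = max(1, int(np.floor(val_frac * len(idx))))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    train_idx = np.sort(np.concatenate(train_idx))
    val_idx = np.sort(np.concatenate(val_idx))
    return ds.subset(train_idx), ds.subset(val_idx)


def _bilinear_gather(image, sy, sx):
    """Sample ``image`` at fractional (sy, sx); out-of-canvas corners weigh 0."""
    H, W = image.shape[:2]
    y0 = np.floor(sy).astype(int)
    x0 = np.floor(sx).astype(int)
    dy, dx = sy - y0, sx - x0
    out = np.zeros(sy.shape + image.shape[2:], dtype=np.float64)
    for oy, ox, w in ((0, 0, (1 - dy) * (1 - dx)), (0, 1, (1 - dy) * dx),
                      (1, 0, dy * (1 - dx)), (1, 1, dy * dx)):
        yy, xx = y0 + oy, x0 + ox
        inside = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        vals = image[np.clip(yy, 0, H - 1), np.clip(xx, 0, W - 1)]
        weight = (w * inside)
        out += vals * (weight[..., None] if image.ndim == 3 else weight)
    return out


def rotate_image(image, angle_deg):
    """Counterclockwise rotation about the image center, bilinear, zero fill."""
    image = np.asarray(image, dtype=np.float64)
    if angle_deg % 360 == 0:
        return image.copy()
    H, W = image.shape[:2]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    cos, sin = np.cos(theta), np.sin(theta)
    yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    # inverse map: source coordinates that land on each output pixel
    sy = cy + (yy - cy) * cos - (xx - cx) * sin
    sx = cx + (yy - cy) * sin + (xx - cx) * cos
    return _bilinear_gather(image, sy, sx)


def shift_image(image, dy, dx):
    """Integer translation with zero fill (pixels shifted off the canvas are
    dropped)."""
    out = np.zeros_like(image)
    H, W = image.shape[:2]
    ys_src = slice(max(0, -dy), min(H, H - dy))
    ys_dst = slice(max(0, dy), min(H, H + dy))
    xs_src = slice(max(0, -dx), min(W, W - dx))
    xs_dst = slice(max(0, dx), min(W, W + dx))
    out[ys_dst, xs_dst] = image[ys_src, xs_src]
    return out


def random_transform(image, max_shift, max_angle, rng):
    """Random rotation then integer translation, the augmentation used for
    transformation-robustness experiments.

    The tuple notation (t, theta) maps to (max_shift, max_angle): shifts are
    drawn uniformly from the integers [-t, t] per axis and the angle
    uniformly from [-theta, +theta] degrees.  (0, 0) is the identity.
    """
    if max_shift < 0 or max_angle < 0:
        raise ValueError("max_shift and max_angle must be >= 0")
    image = np.asarray(image)
    dtype = image.dtype
    dy = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
    dx = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
    angle = float(rng.uniform(-max_angle, max_angle)) if max_angle else 0.0
    out = image.astype(np.float64)
    if angle != 0.0:
        out = rotate_image(out, angle)
    if dy or dx:
        out = shift_image(out, dy, dx)
    if np.issubdtype(dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255)
    return out.astype(dtype)


# ---------------------------------------------------------------------------
# synthetic textured dataset
# ---------------------------------------------------------------------------

def _stripe_pattern(size, width, phase, orientation):
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    if orientation == "h":
        t = yy
    elif orientation == "v":
        t = xx
    elif orientation == "d":
        t = yy + xx
    elif orientation == "a":
        t = yy - xx
    else:
        raise ValueError(orientation)
    return ((t + phase) // width) % 2


def _class_image(cls, size, rng):
    """One uint8 (size, size, 3) archetype image for a texture class.

    All classes are built from flat same-valued pixel runs so the 2x2 texton
    detector fires densely on noise-free samples.
    """
    c1 = rng.integers(0, 96, 3)
    c2 = rng.integers(160, 256, 3)
    width = int(rng.integers(2, 5))
    phase = int(rng.integers(0, 2 * width))
    img = np.zeros((size, size), dtype=np.int64)
    if cls in ("hstripe", "vstripe", "dstripe", "astripe"):
        img = _stripe_pattern(size, width,
                              phase, {"hstripe": "h", "vstripe": "v",
                                      "dstripe": "d", "astripe": "a"}[cls])
    elif cls == "checker":
        cell = int(rng.integers(2, 5))
        yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        img = (((yy + phase) // cell) + ((xx + phase) // cell)) % 2
    elif cls == "blob":
        cy, cx = rng.integers(size // 4, 3 * size // 4, 2)
        r = int(rng.integers(size // 6, size // 3))
        yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        img = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r).astype(np.int64)
    elif cls == "ring":
        cy = cx = size // 2
        r = int(rng.integers(size // 4, size // 2 - 2))
        w = int(rng.integers(2, 4))
        yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img = ((d2 <= r * r) & (d2 >= (r - w) ** 2)).astype(np.int64)
    elif cls == "gradient":
        bands = int(rng.integers(4, 9))
        xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")[1]
        levels = (xx * bands) // size
        lo, hi = sorted(rng.integers(0, 256, 2))
        vals = np.linspace(lo, hi, bands).astype(np.uint8)
        return np.repeat(vals[levels][:, :, None], 3, axis=2)
    elif cls == "speckle":
        cell = int(rng.integers(3, 6))
        small = rng.integers(0, 2, (size // cell + 1, size // cell + 1))
        img = np.repeat(np.repeat(small, cell, 0), cell, 1)[:size, :size]
    elif cls == "grid":
        cell = int(rng.integers(3, 6))
        yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        img = (((yy + phase) % cell == 0) | ((xx + phase) % cell == 0)).astype(np.int64)
    else:
        raise ValueError(f"unknown class archetype {cls}")
    out = np.where(img[:, :, None].astype(bool), c2[None, None, :],
                   c1[None, None, :])
    return out.astype(np.uint8)


_CLASS_ORDER = ["hstripe", "vstripe", "dstripe", "checker", "blob", "ring",
                "gradient", "speckle", "astripe", "grid"]


def synth_textured_dataset(n, n_classes=4, seed=0, noise_frac=0.05, size=32):
    """Balanced multi-class 32x32x3 textured images.

    Class archetypes are texture families with abundant equal-neighbor pixel
    runs (stripes, checkerboards, ...) so the texton operator fires
    informatively; colors, phases and stripe widths vary per sample, and
    ``noise_frac`` of the pixels are replaced by uniform noise.
    """
    if n_classes not in (2, 4, 10):
        raise ValueError("n_classes must be 2, 4 or 10")
    if n < n_classes:
        raise ValueError("need at least one sample per class")
    rng = np.random.default_rng(seed)
    names = _CLASS_ORDER[:n_classes]
    labels = np.arange(n) % n_classes  # balanced to within 1
    images = np.empty((n, size, size, 3), dtype=np.uint8)
    for i, lab in enumerate(labels):
        img = _class_image(names[lab], size, rng)
        if noise_frac > 0:
            noisy = rng.random((size, size)) < noise_frac
            img = img.copy()
            img[noisy] = rng.integers(0, 256, (int(noisy.sum()), 3))
        images[i] = img
    order = rng.permutation(n)
    return ImageDataset(images[order], labels[order], class_names=names)
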