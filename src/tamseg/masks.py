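"""Mask containers and their file formats.

Two kinds of masks run through the whole pipeline:

* **binary masks** — 2-D boolean arrays, ``True`` on macrophage (foreground)
  pixels.  Stored on disk as 8-bit PNG with values 0/255.
* **label masks** — 2-D non-negative integer arrays; 0 is background and each
  positive integer is one cell instance.  Stored as single-channel 16-bit PNG
  or TIFF.

Instances of a label mask are pairwise disjoint by construction (one integer
per pixel) and, after :func:`relabel_canonical`, their ids form the contiguous
range ``1..M``.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "as_binary_mask",
    "as_label_mask",
    "binarize",
    "relabel_canonical",
    "instance_ids",
    "read_binary_mask",
    "write_binary_mask",
    "read_label_mask",
    "write_label_mask",
    "read_image",
    "write_image",
    "read_weight_map",
    "write_weight_map",
]


def as_binary_mask(pixels) -> np.ndarray:
    """Validate and coerce ``pixels`` to a 2-D boolean mask."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"binary mask must be 2-D, got shape {arr.shape}")
    return arr.astype(bool)


def as_label_mask(pixels) -> np.ndarray:
    """Validate and coerce ``pixels`` to a 2-D non-negative integer label mask."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise ValueError("label mask must contain integers")
        arr = arr.astype(np.int64)
    if arr.size and arr.min() < 0:
        raise ValueError("label mask must be non-negative (0 = background)")
    return arr.astype(np.int32, copy=False)


def binarize(labels) -> np.ndarray:
    """Foreground of a label mask: union of all instances."""
    return as_label_mask(labels) > 0


def instance_ids(labels) -> np.ndarray:
    """Sorted array of instance ids present (background excluded)."""
    ids = np.unique(as_label_mask(labels))
    return ids[ids > 0]


def relabel_canonical(labels) -> np.ndarray:
    """Remap instance ids to the contiguous range ``1..M``.

    The pixel partition is preserved, ids are assigned in increasing order of
    the original ids.  Idempotent; all overlap metrics are invariant under it.
    """
    arr = as_label_mask(labels)
    ids = np.unique(arr)
    ids = ids[ids > 0]
    if ids.size == 0:
        return arr.copy()
    lut = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return lut[arr]


# ---------------------------------------------------------------------------
# I/O — 8-bit PNG for binary masks, 16-bit PNG/TIFF for label masks,
# 32-bit float TIFF for weight maps.

def write_binary_mask(path: str | os.PathLike, mask) -> None:
    mask = as_binary_mask(mask)
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)


def read_binary_mask(path: str | os.PathLike) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 127


def write_label_mask(path: str | os.PathLike, labels) -> None:
    labels = as_label_mask(labels)
    if labels.size and labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances cannot be stored as 16-bit")
    arr = labels.astype(np.uint16)
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)  # uint16 → 16-bit grayscale PNG


def read_label_mask(path: str | os.PathLike) -> np.ndarray:
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    return as_label_mask(arr)


def write_image(path: str | os.PathLike, image) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        image = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(image).save(path)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read an RGB tile as uint8 H×W×3."""
    return np.asarray(Image.open(path).convert("RGB"))


def write_weight_map(path: str | os.PathLike, weights) -> None:
    tifffile.imwrite(os.fspath(path), np.asarray(weights, dtype=np.float32))


def read_weight_map(path: str | os.PathLike) -> np.ndarray:
    return tifffile.imread(os.fspath(path)).astype(np.float32)
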