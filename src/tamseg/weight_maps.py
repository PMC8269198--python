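"""Per-pixel loss weights that push semantic models to separate nearby cells.

The weighted-semantic strategy keeps the architecture unchanged and instead
reshapes the pixel cross-entropy: background pixels lying in the *gap* between
two macrophages that are closer than ``proximity_px`` (10 px by default) are
penalized about three times as much when misclassified, forcing the model to
keep the separating background corridor open; pixels on the blurry *edge* of a
cell get a reduced penalty, since the hand-drawn contours are least reliable
there.

A background pixel is a gap pixel when its Euclidean distances to the nearest
pixels of its two nearest *distinct* instances are both below ``proximity_px``.
Edge pixels are foreground pixels 8-adjacent to background (band depth
configurable).  Everything else keeps ``base_weight``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .masks import as_binary_mask, as_label_mask, instance_ids

__all__ = [
    "WeightMap",
    "compute_weight_map",
    "weighted_pixel_cross_entropy",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class WeightMap:
    """Positive per-pixel loss multipliers plus the parameters that made them."""

    weights: np.ndarray
    base_weight: float = 1.0
    gap_weight: float = 3.0
    edge_weight: float = 0.5
    proximity_px: int = 10

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float32)
        if self.weights.ndim != 2:
            raise ValueError("weight map must be 2-D")
        if self.weights.size and self.weights.min() <= 0:
            raise ValueError("all weights must be positive")

    @property
    def shape(self):
        return self.weights.shape


def _edge_band(foreground: np.ndarray, depth: int) -> np.ndarray:
    """Foreground pixels within ``depth`` erosions of the background (8-conn)."""
    eroded = foreground
    for _ in range(depth):
        # border_value=1: a cell cut by the tile border is not "edge" there
        eroded = ndimage.binary_erosion(eroded, structure=_EIGHT, border_value=1)
    return foreground & ~eroded


def compute_weight_map(
    truth,
    proximity_px: int = 10,
    gap_weight: float = 3.0,
    edge_weight: float = 0.5,
    base_weight: float = 1.0,
    edge_band_px: int = 1,
    edge_side: str = "foreground",
) -> WeightMap:
    """Build the gap/edge penalty map for one ground-truth label mask.

    Parameters
    ----------
    truth : label mask
        Ground-truth instances; the map depends only on their geometry.
    proximity_px : int
        Strict distance threshold (px): a background pixel is a gap pixel when
        its two nearest distinct instances are each closer than this.
    gap_weight, edge_weight, base_weight : float
        Multipliers; gap and edge are applied on top of ``base_weight``.
    edge_band_px : int
        Depth of the reduced-penalty edge band, in erosion steps.
    edge_side : {"foreground", "both"}
        Whether the reduced edge penalty covers only foreground boundary
        pixels or also the background pixels 8-adjacent to a cell.
    """
    if proximity_px < 1:
        raise ValueError("proximity_px must be >= 1")
    for name, v in (("gap_weight", gap_weight), ("edge_weight", edge_weight),
                    ("base_weight", base_weight)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if edge_side not in ("foreground", "both"):
        raise ValueError("edge_side must be 'foreground' or 'both'")

    labels = as_label_mask(truth)
    fg = labels > 0
    weights = np.full(labels.shape, base_weight, dtype=np.float32)

    # Reduced penalty on the blurry cell rim.
    edge = _edge_band(fg, edge_band_px)
    if edge_side == "both":
        dil = ndimage.binary_dilation(fg, structure=_EIGHT, iterations=edge_band_px)
        edge = edge | (dil & ~fg)
    weights[edge] = base_weight * edge_weight

    # Gap corridor: background pixels whose two nearest distinct instances
    # are both strictly closer than proximity_px (Euclidean distances to the
    # instances' pixel sets, via one EDT per instance).
    ids = instance_ids(labels)
    if ids.size >= 2:
        dists = np.stack(
            [ndimage.distance_transform_edt(labels != k) for k in ids]
        )
        two_nearest = np.partition(dists, 1, axis=0)[:2]
        gap = (two_nearest < proximity_px).all(axis=0) & ~fg
        weights[gap] = base_weight * gap_weight

    return WeightMap(
        weights,
        base_weight=base_weight,
        gap_weight=gap_weight,
        edge_weight=edge_weight,
        proximity_px=proximity_px,
    )


def weighted_pixel_cross_entropy(class_scores, truth, weights=None) -> float:
    """Mean over pixels of ``weight(x) · CE(x)`` for a two-class score map.

    ``class_scores`` is ``(2, H, W)`` or ``(H, W, 2)`` of raw scores (logits);
    a softmax over the class axis defines the per-pixel probability of
    {background, foreground}.  ``truth`` is the boolean foreground mask.  With
    unit weights this is the ordinary pixel cross-entropy.
    """
    scores = np.asarray(class_scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("class scores must be finite")
    if scores.ndim != 3:
        raise ValueError("class scores must be 3-D with a class axis of size 2")
    if scores.shape[0] == 2:
        scores = np.moveaxis(scores, 0, -1)
    if scores.shape[-1] != 2:
        raise ValueError("class axis must have size 2")
    t = as_binary_mask(truth)
    if scores.shape[:2] != t.shape:
        raise ValueError(
            f"score grid {scores.shape[:2]} does not match truth {t.shape}"
        )
    if weights is None:
        w = np.ones(t.shape, dtype=np.float64)
    else:
        w = weights.weights if isinstance(weights, WeightMap) else np.asarray(weights)
        if w.shape != t.shape:
            raise ValueError(f"weights {w.shape} do not match truth {t.shape}")
        w = w.astype(np.float64)

    shifted = scores - scores.max(axis=-1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=-1))
    true_score = np.where(t, shifted[..., 1], shifted[..., 0])
    ce = logz - true_score
    return float(np.mean(w * ce))
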