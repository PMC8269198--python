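"""From network outputs to instances, and per-instance morphometry.

Semantic strategies produce a foreground probability map; instances are its
8-connected components above a threshold.  The instance strategy produces a
pixel embedding field; foreground pixels are clustered in embedding space
with mean shift (bandwidth defaulting to the pull margin of the training
loss, the natural within-cluster scale) and each cluster becomes one
instance.  A minimum-size filter removes speckle components.

Morphometry reports the quantity the pipeline ultimately exists to measure:
per-cell area (in px and, given a pixel size, in μm²), which separates the
prognostically distinct small (S) and large (L) macrophage classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from sklearn.cluster import MeanShift

from .masks import as_binary_mask, as_label_mask, relabel_canonical

__all__ = ["InstanceStats", "semantic_to_instances", "cluster_embeddings",
           "instance_stats", "classify_by_area"]

_EIGHT = np.ones((3, 3), dtype=bool)


def _filter_small(labels: np.ndarray, min_size: int) -> np.ndarray:
    if min_size <= 1:
        return relabel_canonical(labels)
    ids, counts = np.unique(labels, return_counts=True)
    drop = ids[(ids > 0) & (counts < min_size)]
    if drop.size:
        labels = labels.copy()
        labels[np.isin(labels, drop)] = 0
    return relabel_canonical(labels)


def semantic_to_instances(class_scores, threshold: float = 0.5,
                          min_size: int = 10) -> np.ndarray:
    """Threshold a foreground-probability map and label 8-connected components.

    This is how a purely semantic model is scored for instance separation:
    touching cells necessarily fuse into one component.
    """
    prob = np.asarray(class_scores, dtype=np.float64)
    if prob.ndim != 2:
        raise ValueError("expected a 2-D foreground probability map")
    fg = prob > threshold
    labels = measure.label(fg, connectivity=2)
    return _filter_small(labels.astype(np.int32), min_size)


def cluster_embeddings(embeddings, foreground, bandwidth: float,
                       min_size: int = 10, max_points: int = 3000,
                       merge_margin_factor: float = 2.0,
                       merge_size_ratio: float = 0.5,
                       seed: int = 0) -> np.ndarray:
    """Mean-shift clustering of foreground-pixel embeddings into instances.

    ``embeddings`` is H×W×n; only pixels where ``foreground`` is True are
    clustered, background stays 0.  For large foregrounds the mean-shift fit
    runs on a random subsample of ``max_points`` pixels and the remaining
    pixels are assigned to the nearest cluster center.

    Because the training loss is hinged, pixels at the interface of two
    touching cells can settle into a small intermediate mode between the two
    real clusters.  A cluster whose centroid lies within
    ``merge_margin_factor · bandwidth`` of a larger cluster's centroid and
    whose size is below ``merge_size_ratio`` of that cluster is treated as
    such a boundary artifact and merged into it; genuine instances are
    unaffected since their centroids are pushed at least ``2·delta_d`` apart,
    beyond the margin band.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    emb = np.asarray(embeddings, dtype=np.float64)
    if emb.ndim != 3:
        raise ValueError("embeddings must be H×W×n")
    fg = as_binary_mask(foreground)
    if emb.shape[:2] != fg.shape:
        raise ValueError("embedding and foreground shapes differ")
    labels = np.zeros(fg.shape, dtype=np.int32)
    rows, cols = np.nonzero(fg)
    if rows.size == 0:
        return labels
    x = emb[rows, cols]
    if rows.size > max_points:
        rng = np.random.default_rng(seed)
        fit_idx = rng.choice(rows.size, size=max_points, replace=False)
    else:
        fit_idx = slice(None)
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=rows.size > 500,
                   cluster_all=True)
    try:
        ms.fit(x[fit_idx])
    except ValueError:
        # bin seeding can yield no seeds for tight point clouds
        ms = MeanShift(bandwidth=bandwidth, cluster_all=True)
        ms.fit(x[fit_idx])
    assignment = ms.predict(x)

    # merge subordinate boundary modes into their parent cluster
    ids, sizes = np.unique(assignment, return_counts=True)
    if ids.size > 1 and merge_margin_factor > 0:
        centroids = np.stack([x[assignment == k].mean(axis=0) for k in ids])
        relabel = {k: k for k in ids}
        order = np.argsort(sizes)  # smallest first
        for pos in order:
            k = ids[pos]
            best, best_d = None, np.inf
            for pos2 in range(len(ids)):
                k2 = ids[pos2]
                if relabel[k2] != k2 or k2 == k:
                    continue
                if sizes[pos] >= merge_size_ratio * sizes[pos2]:
                    continue
                d = np.linalg.norm(centroids[pos] - centroids[pos2])
                if d < merge_margin_factor * bandwidth and d < best_d:
                    best, best_d = k2, d
            if best is not None:
                relabel[k] = best
                sizes[np.searchsorted(ids, best)] += sizes[pos]
        # resolve chains
        def root(k):
            while relabel[k] != k:
                k = relabel[k]
            return k
        assignment = np.array([root(k) for k in assignment])

    labels[rows, cols] = assignment + 1
    return _filter_small(labels, min_size)


@dataclass
class InstanceStats:
    """Morphometry of one cell instance."""

    instance_id: int
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    boundary_px: int
    area_um2: Optional[float] = None


def instance_stats(mask, um_per_px: Optional[float] = None) -> list[InstanceStats]:
    """One record per instance: exact pixel area, centroid, boundary length.

    ``area_um2 = area_px · um_per_px²`` when a pixel size is given.
    """
    labels = relabel_canonical(as_label_mask(mask))
    out: list[InstanceStats] = []
    for prop in measure.regionprops(labels):
        sil = labels == prop.label
        interior = ndimage.binary_erosion(sil, structure=_EIGHT)
        out.append(InstanceStats(
            instance_id=int(prop.label),
            area_px=int(prop.area),
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            boundary_px=int(np.count_nonzero(sil & ~interior)),
            area_um2=(float(prop.area) * um_per_px**2
                      if um_per_px is not None else None),
        ))
    return out


def classify_by_area(stats: list[InstanceStats], cutoff_um2: float) -> list[str]:
    """Label instances ``"S"`` (area < cutoff) or ``"L"`` (area ≥ cutoff).

    The boundary is closed on the right: an area exactly at the cutoff is L.
    """
    if cutoff_um2 <= 0:
        raise ValueError("cutoff_um2 must be positive")
    out = []
    for s in stats:
        if s.area_um2 is None:
            raise ValueError(
                f"instance {s.instance_id} has no calibrated area; pass "
                "um_per_px to instance_stats")
        out.append("S" if s.area_um2 < cutoff_um2 else "L")
    return out
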