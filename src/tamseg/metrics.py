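"""Segmentation quality statistics: IoU, Dice, Best Dice and Symmetric Best Dice.

IoU measures semantic quality — how well predicted foreground overlaps true
foreground:

    IoU(P, T) = |P ∩ T| / |P ∪ T|

Dice is its monotone companion, ``2|P∩T| / (|P|+|T|) = 2·IoU/(1+IoU)``.

Best Dice lifts Dice to instance labelings: for every instance of mask ``a``
take the best instance-wise Dice against any instance of mask ``b`` and
average.  It is *not* commutative — a mask with spurious extra instances can
still score BD(a,b)=1 in one direction.  Symmetric Best Dice (SBD) takes the
minimum of the two directions and is the instance-separation score reported
throughout this package.

Empty-mask conventions (the clinical tiles are never empty, so these are
package conventions): both masks empty → 1.0, exactly one empty → 0.0.  A
perfect background prediction is therefore not penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .masks import as_binary_mask, as_label_mask, binarize, relabel_canonical

__all__ = [
    "iou",
    "dice",
    "best_dice",
    "sbd",
    "MetricReport",
    "evaluate_dataset",
]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(
            f"mask shapes differ: {a.shape} vs {b.shape}"
        )


def iou(predicted, truth) -> float:
    """Intersection over union of two binary masks, in [0, 1]."""
    p = as_binary_mask(predicted)
    t = as_binary_mask(truth)
    _check_shapes(p, t)
    union = np.count_nonzero(p | t)
    if union == 0:
        return 1.0
    return np.count_nonzero(p & t) / union


def dice(predicted, truth) -> float:
    """Dice score ``2|P∩T|/(|P|+|T|)`` of two binary masks, in [0, 1]."""
    p = as_binary_mask(predicted)
    t = as_binary_mask(truth)
    _check_shapes(p, t)
    total = np.count_nonzero(p) + np.count_nonzero(t)
    if total == 0:
        return 1.0
    return 2.0 * np.count_nonzero(p & t) / total


def _pairwise_dice(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int, int]:
    """All instance-vs-instance Dice values between two label masks.

    Returns ``(D, M, N)`` where ``D[i, j]`` is the Dice between instance
    ``i+1`` of ``a`` and instance ``j+1`` of ``b`` (canonical ids).  Computed
    from the joint label contingency table, so cost is one pass over pixels.
    """
    a = relabel_canonical(as_label_mask(a))
    b = relabel_canonical(as_label_mask(b))
    _check_shapes(a, b)
    m = int(a.max())
    n = int(b.max())
    if m == 0 or n == 0:
        return np.zeros((m, n)), m, n
    joint = np.bincount(
        (a.astype(np.int64) * (n + 1) + b.astype(np.int64)).ravel(),
        minlength=(m + 1) * (n + 1),
    ).reshape(m + 1, n + 1)
    inter = joint[1:, 1:].astype(np.float64)
    area_a = joint[1:, :].sum(axis=1, dtype=np.float64)
    area_b = joint[:, 1:].sum(axis=0, dtype=np.float64)
    return 2.0 * inter / (area_a[:, None] + area_b[None, :]), m, n


def best_dice(a, b) -> float:
    """Mean over instances of ``a`` of the best Dice against instances of ``b``.

    Raises if ``a`` has no instances (the mean is undefined); returns 0 when
    only ``b`` is empty.
    """
    d, m, n = _pairwise_dice(a, b)
    if m == 0:
        raise ValueError("best_dice: first mask has no instances")
    if n == 0:
        return 0.0
    return float(d.max(axis=1).mean())


def sbd(a, b) -> float:
    """Symmetric Best Dice ``min(BD(a,b), BD(b,a))``.

    Both masks empty of instances → 1.0; exactly one empty → 0.0.
    """
    d, m, n = _pairwise_dice(a, b)
    if m == 0 and n == 0:
        return 1.0
    if m == 0 or n == 0:
        return 0.0
    return float(min(d.max(axis=1).mean(), d.max(axis=0).mean()))


@dataclass
class MetricReport:
    """Per-image and dataset-level IoU/SBD, on the percent scale.

    ``per_image`` holds ``(image_id, iou, sbd)`` with fractions in [0, 1];
    the aggregate fields are percentages.  The standard deviation is the
    per-image *sample* standard deviation (ddof=1; 0 for a single image).
    """

    per_image: list[tuple[str, float, float]] = field(default_factory=list)
    model: str = ""
    strategy: str = ""

    @property
    def iou_values(self) -> np.ndarray:
        return np.array([v for _, v, _ in self.per_image], dtype=float)

    @property
    def sbd_values(self) -> np.ndarray:
        return np.array([v for _, _, v in self.per_image], dtype=float)

    @staticmethod
    def _mean(v: np.ndarray) -> float:
        return float(np.mean(v) * 100.0)

    @staticmethod
    def _stdev(v: np.ndarray) -> float:
        if v.size < 2:
            return 0.0
        return float(np.std(v, ddof=1) * 100.0)

    @property
    def iou_mean(self) -> float:
        return self._mean(self.iou_values)

    @property
    def iou_stdev(self) -> float:
        return self._stdev(self.iou_values)

    @property
    def sbd_mean(self) -> float:
        return self._mean(self.sbd_values)

    @property
    def sbd_stdev(self) -> float:
        return self._stdev(self.sbd_values)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "strategy": self.strategy,
            "iou_mean": round(self.iou_mean, 4),
            "iou_stdev": round(self.iou_stdev, 4),
            "sbd_mean": round(self.sbd_mean, 4),
            "sbd_stdev": round(self.sbd_stdev, 4),
            "per_image": [
                {"image_id": i, "iou": v, "sbd": s} for i, v, s in self.per_image
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricReport":
        rep = cls(model=d.get("model", ""), strategy=d.get("strategy", ""))
        rep.per_image = [
            (e["image_id"], float(e["iou"]), float(e["sbd"]))
            for e in d["per_image"]
        ]
        return rep

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MetricReport":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def summary_row(self) -> dict:
        """One row of the summary table: model, strategy, IoU/SBD mean and stdev."""
        return {
            "model": self.model,
            "strategy": self.strategy,
            "iou_mean": round(self.iou_mean, 4),
            "iou_stdev": round(self.iou_stdev, 4),
            "sbd_mean": round(self.sbd_mean, 4),
            "sbd_stdev": round(self.sbd_stdev, 4),
        }


def reports_to_csv(reports: Sequence[MetricReport], path) -> pd.DataFrame:
    """Write one summary CSV with a row per report (model/strategy grid)."""
    df = pd.DataFrame([r.summary_row() for r in reports])
    df.to_csv(path, index=False)
    return df


def evaluate_dataset(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]],
    image_ids: Sequence[str] | None = None,
    model: str = "",
    strategy: str = "",
) -> MetricReport:
    """Score ``(predicted, truth)`` label-mask pairs image by image.

    IoU is computed on binarized masks (any instance → foreground) so that
    semantic and instance strategies share a single IoU definition; SBD on the
    instance labelings.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_dataset: empty list of mask pairs")
    if image_ids is None:
        image_ids = [f"image_{i:04d}" for i in range(len(pairs))]
    report = MetricReport(model=model, strategy=strategy)
    for img_id, (pred, truth) in zip(image_ids, pairs):
        pred = as_label_mask(pred)
        truth = as_label_mask(truth)
        _check_shapes(pred, truth)
        report.per_image.append(
            (img_id, iou(binarize(pred), binarize(truth)), sbd(pred, truth))
        )
    return report
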