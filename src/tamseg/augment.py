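"""Data augmentation, patch sampling and the patient-level dataset split.

Training uses aggressive augmentation: rotation at any angle, morphological
transforms (scale/shear/warp) with factors drawn from ``(0.8, 1.3)``, and
photometric jitter (color, contrast, hue, exposure).  Every geometric
transform is applied identically to the image (bilinear), the instance label
mask (nearest neighbour, so ids stay integral) and the weight map (bilinear);
photometric transforms touch the image only.

The dataset split is at the *patient* level — all tiles of one patient land in
a single partition — with 70/15/15 train/validation/test fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from skimage import color as skcolor
from skimage import transform as sktransform
from scipy import ndimage

from .masks import as_label_mask
from .weight_maps import WeightMap

__all__ = [
    "Sample",
    "AugmentationConfig",
    "augment",
    "sample_patch",
    "split_by_patient",
]

logger = logging.getLogger(__name__)


@dataclass
class Sample:
    """One RGB tile with its ground truth (and optional weight map)."""

    image: np.ndarray  # H×W×3, float in [0,1] or uint8
    truth: np.ndarray  # H×W int label mask
    weight_map: Optional[WeightMap] = None
    patient_id: str = ""
    sample_id: str = ""

    def __post_init__(self):
        self.truth = as_label_mask(self.truth)
        if self.image.shape[:2] != self.truth.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and truth {self.truth.shape} disagree"
            )
        if self.weight_map is not None and self.weight_map.shape != self.truth.shape:
            raise ValueError("weight map shape does not match truth")
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")

    @property
    def shape(self):
        return self.truth.shape


@dataclass
class AugmentationConfig:
    """Which transforms run and how strong they are.

    ``morph_factor_range`` bounds the random factor used by the morphological
    transforms (scaling, shear, warp); rotation may be any angle.  Each
    enabled transform fires independently with probability ``apply_prob`` per
    sample.  Photometric amplitudes default to ±10 %.
    """

    morph_factor_range: tuple[float, float] = (0.8, 1.3)
    rotation: bool = True
    scaling: bool = True
    shear: bool = True
    warp: bool = True
    color_jitter: bool = True
    contrast: bool = True
    hue: bool = True
    exposure: bool = True
    apply_prob: float = 0.5
    photometric_amplitude: float = 0.10
    hue_amplitude: float = 0.05
    max_retries: int = 5

    def __post_init__(self):
        lo, hi = self.morph_factor_range
        if not (0 < lo < hi):
            raise ValueError("morph_factor_range must satisfy 0 < low < high")

    @classmethod
    def disabled(cls) -> "AugmentationConfig":
        return cls(rotation=False, scaling=False, shear=False, warp=False,
                   color_jitter=False, contrast=False, hue=False, exposure=False)


def _as_float_image(image: np.ndarray) -> np.ndarray:
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0
    return image.astype(np.float64)


def _geometric(sample: Sample, cfg: AugmentationConfig, rng: np.random.Generator):
    """One random affine (+ optional elastic warp) applied congruently."""
    h, w = sample.shape
    angle = 0.0
    scale = 1.0
    shear = 0.0
    lo, hi = cfg.morph_factor_range
    if cfg.rotation and rng.random() < cfg.apply_prob:
        angle = rng.uniform(0.0, 2.0 * np.pi)
    if cfg.scaling and rng.random() < cfg.apply_prob:
        scale = rng.uniform(lo, hi)
    if cfg.shear and rng.random() < cfg.apply_prob:
        # shear angle mapped from the morphological factor interval onto a
        # modest +-(hi-1) rad range
        shear = rng.uniform(-(hi - 1.0), hi - 1.0)

    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (
        sktransform.AffineTransform(translation=-center)
        + sktransform.AffineTransform(rotation=angle, scale=scale, shear=shear)
        + sktransform.AffineTransform(translation=center)
    )

    image = _as_float_image(sample.image)
    img_out = sktransform.warp(image, tf.inverse, order=1, mode="reflect",
                               preserve_range=True)
    lab_out = sktransform.warp(sample.truth.astype(np.float64), tf.inverse,
                               order=0, mode="constant", cval=0.0,
                               preserve_range=True).astype(np.int32)
    wm_out = None
    if sample.weight_map is not None:
        wm_out = sktransform.warp(
            sample.weight_map.weights.astype(np.float64), tf.inverse,
            order=1, mode="edge", preserve_range=True)

    if cfg.warp and rng.random() < cfg.apply_prob:
        # elastic displacement field, amplitude tied to the morph factor range
        amp = rng.uniform(0.0, (hi - lo)) * 4.0
        sigma = 12.0
        dy = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma) * amp
        dx = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma) * amp
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.stack([rr + dy, cc + dx])
        img_out = np.stack(
            [ndimage.map_coordinates(img_out[..., c], coords, order=1,
                                     mode="reflect") for c in range(3)],
            axis=-1,
        )
        lab_out = ndimage.map_coordinates(
            lab_out.astype(np.float64), coords, order=0, mode="constant",
            cval=0.0).astype(np.int32)
        if wm_out is not None:
            wm_out = ndimage.map_coordinates(wm_out, coords, order=1,
                                             mode="nearest")
    return img_out, lab_out, wm_out


def _photometric(image: np.ndarray, cfg: AugmentationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    a = cfg.photometric_amplitude
    out = image
    if cfg.color_jitter and rng.random() < cfg.apply_prob:
        gains = rng.uniform(1.0 - a, 1.0 + a, size=3)
        out = out * gains
    if cfg.contrast and rng.random() < cfg.apply_prob:
        f = rng.uniform(1.0 - a, 1.0 + a)
        mean = out.mean(axis=(0, 1), keepdims=True)
        out = (out - mean) * f + mean
    if cfg.hue and rng.random() < cfg.apply_prob:
        shift = rng.uniform(-cfg.hue_amplitude, cfg.hue_amplitude)
        hsv = skcolor.rgb2hsv(np.clip(out, 0.0, 1.0))
        hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
        out = skcolor.hsv2rgb(hsv)
    if cfg.exposure and rng.random() < cfg.apply_prob:
        out = out * rng.uniform(1.0 - a, 1.0 + a)
    return np.clip(out, 0.0, 1.0)


def augment(sample: Sample, config: AugmentationConfig,
            rng: np.random.Generator) -> Sample:
    """Randomly transformed copy of ``sample``; deterministic given ``rng``.

    If the geometric transform wipes out every instance the draw is retried a
    bounded number of times; after that the (all-background) result is
    returned with a warning.
    """
    had_fg = bool((sample.truth > 0).any())
    for attempt in range(config.max_retries + 1):
        img, lab, wm = _geometric(sample, config, rng)
        if not had_fg or (lab > 0).any():
            break
        if attempt == config.max_retries:
            logger.warning(
                "augment: all instances transformed out of frame after %d retries",
                config.max_retries,
            )
    img = _photometric(img, config, rng)
    wm_obj = None
    if sample.weight_map is not None:
        src = sample.weight_map
        wm_obj = WeightMap(wm, base_weight=src.base_weight,
                           gap_weight=src.gap_weight,
                           edge_weight=src.edge_weight,
                           proximity_px=src.proximity_px)
    return Sample(image=img, truth=lab, weight_map=wm_obj,
                  patient_id=sample.patient_id, sample_id=sample.sample_id)


def sample_patch(sample: Sample, size: int = 224,
                 rng: np.random.Generator | None = None) -> Sample:
    """Axis-aligned ``size``×``size`` crop at a uniformly random valid offset."""
    h, w = sample.shape
    if h < size or w < size:
        raise ValueError(f"tile {h}x{w} is smaller than the patch size {size}")
    rng = rng or np.random.default_rng()
    r0 = int(rng.integers(0, h - size + 1))
    c0 = int(rng.integers(0, w - size + 1))
    wm = None
    if sample.weight_map is not None:
        src = sample.weight_map
        wm = WeightMap(src.weights[r0:r0 + size, c0:c0 + size],
                       base_weight=src.base_weight, gap_weight=src.gap_weight,
                       edge_weight=src.edge_weight,
                       proximity_px=src.proximity_px)
    return Sample(image=sample.image[r0:r0 + size, c0:c0 + size],
                  truth=sample.truth[r0:r0 + size, c0:c0 + size],
                  weight_map=wm, patient_id=sample.patient_id,
                  sample_id=f"{sample.sample_id}@{r0},{c0}")


def split_by_patient(
    samples: Sequence[Sample],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    rng_seed: int = 0,
) -> tuple[list[Sample], list[Sample], list[Sample]]:
    """Patient-disjoint train/validation/test partition.

    Validation and test receive ``round(fraction · n_patients)`` patients
    each; the remainder goes to training.  Deterministic given ``rng_seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    patients = sorted({s.patient_id for s in samples})
    n = len(patients)
    if n < 3:
        raise ValueError(f"need at least 3 patients to split, got {n}")
    rng = np.random.default_rng(rng_seed)
    order = [patients[i] for i in rng.permutation(n)]
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("split leaves an empty partition; need more patients")
    train_p = set(order[:n_train])
    val_p = set(order[n_train:n_train + n_val])
    test_p = set(order[n_train + n_val:])
    train = [s for s in samples if s.patient_id in train_p]
    val = [s for s in samples if s.patient_id in val_p]
    test = [s for s in samples if s.patient_id in test_p]
    return train, val, test
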