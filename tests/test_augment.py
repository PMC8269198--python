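"""Augmentation congruence, determinism, and the patient-level split."""

import numpy as np
import pytest

from tamseg.augment import (AugmentationConfig, Sample, augment, sample_patch,
                            split_by_patient)
from tamseg.weight_maps import WeightMap


def _sample(rng, h=48, w=48, n_inst=3, with_wm=False):
    labels = np.zeros((h, w), np.int32)
    for k in range(1, n_inst + 1):
        r, c = rng.integers(5, h - 10), rng.integers(5, w - 10)
        labels[r:r + 5, c:c + 5] = k
    image = rng.random((h, w, 3))
    wm = WeightMap(rng.uniform(0.5, 3.0, (h, w))) if with_wm else None
    return Sample(image=image, truth=labels, weight_map=wm,
                  patient_id="p0", sample_id="s0")


def test_disabled_config_is_identity(rng):
    s = _sample(rng)
    out = augment(s, AugmentationConfig.disabled(), np.random.default_rng(0))
    assert np.allclose(out.image, s.image)
    assert np.array_equal(out.truth, s.truth)


def test_same_seed_bit_identical(rng):
    s = _sample(rng, with_wm=True)
    cfg = AugmentationConfig()
    a = augment(s, cfg, np.random.default_rng(7))
    b = augment(s, cfg, np.random.default_rng(7))
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.truth, b.truth)
    assert np.array_equal(a.weight_map.weights, b.weight_map.weights)


class _ForcedRng:
    """Duck-typed rng driving the geometric draw to an exact 90° rotation."""

    def __init__(self, angle):
        self.angle = angle

    def random(self):
        return 0.0  # every enabled transform fires

    def uniform(self, lo, hi, size=None):
        if lo == 0.0 and hi == pytest.approx(2 * np.pi):
            return self.angle
        mid = (lo + hi) / 2.0
        return np.full(size, mid) if size is not None else mid

    def standard_normal(self, size=None):
        return np.zeros(size) if size is not None else 0.0


def test_quarter_rotation_matches_rot90(rng):
    s = _sample(rng)
    cfg = AugmentationConfig(scaling=False, shear=False, warp=False,
                             color_jitter=False, contrast=False, hue=False,
                             exposure=False)
    out = augment(s, cfg, _ForcedRng(np.pi / 2))
    # warp rotates content by +90° about the center; compare to the exact
    # coordinate remap
    expected = np.rot90(s.truth, k=-1)
    assert np.array_equal(out.truth, expected)
    assert sorted(set(out.truth.ravel()) - {0}) == \
        sorted(set(s.truth.ravel()) - {0})


def test_photometric_leaves_labels_identical(rng):
    s = _sample(rng)
    cfg = AugmentationConfig(rotation=False, scaling=False, shear=False,
                             warp=False, apply_prob=1.0)
    out = augment(s, cfg, np.random.default_rng(5))
    assert np.array_equal(out.truth, s.truth)
    assert not np.allclose(out.image, s.image)


def test_augment_preserves_instance_ids_up_to_cropping(rng):
    s = _sample(rng)
    cfg = AugmentationConfig()
    for seed in range(5):
        out = augment(s, cfg, np.random.default_rng(seed))
        assert set(out.truth.ravel()) - {0} <= set(s.truth.ravel()) - {0}


# ---------------------------------------------------------------------------
# patch sampling


def test_patch_equal_size_is_identity(rng):
    s = _sample(rng, 32, 32)
    out = sample_patch(s, size=32, rng=np.random.default_rng(0))
    assert np.array_equal(out.image, s.image)
    assert np.array_equal(out.truth, s.truth)


def test_patch_congruent_and_reproducible(rng):
    s = _sample(rng, 64, 80, with_wm=True)
    a = sample_patch(s, size=32, rng=np.random.default_rng(3))
    b = sample_patch(s, size=32, rng=np.random.default_rng(3))
    assert np.array_equal(a.image, b.image)
    # image/truth/weights cut at the same offset: locate the crop and compare
    assert a.image.shape == (32, 32, 3)
    found = False
    for r in range(33):
        for c in range(49):
            if np.array_equal(s.image[r:r + 32, c:c + 32], a.image):
                assert np.array_equal(s.truth[r:r + 32, c:c + 32], a.truth)
                assert np.array_equal(
                    s.weight_map.weights[r:r + 32, c:c + 32],
                    a.weight_map.weights)
                found = True
    assert found


def test_patch_offsets_cover_valid_grid(rng):
    s = _sample(rng, 40, 40)
    g = np.random.default_rng(0)
    offsets = set()
    for _ in range(300):
        p = sample_patch(s, size=32, rng=g)
        offsets.add(p.sample_id.split("@")[1])
    # (40-32+1)² = 81 valid offsets, all reachable
    assert len(offsets) > 60


def test_patch_too_small_raises(rng):
    with pytest.raises(ValueError):
        sample_patch(_sample(rng, 32, 32), size=64)


# ---------------------------------------------------------------------------
# patient-level split


def _patients(n, tiles=3):
    out = []
    for p in range(n):
        for t in range(tiles):
            out.append(Sample(image=np.zeros((8, 8, 3)),
                              truth=np.zeros((8, 8), np.int32),
                              patient_id=f"p{p:03d}",
                              sample_id=f"p{p:03d}_t{t}"))
    return out


def test_split_counts_20_patients():
    train, val, test = split_by_patient(_patients(20), rng_seed=0)
    assert len({s.patient_id for s in train}) == 14
    assert len({s.patient_id for s in val}) == 3
    assert len({s.patient_id for s in test}) == 3


def test_split_partition_properties_303_samples():
    samples = _patients(101, 3)
    assert len(samples) == 303
    train, val, test = split_by_patient(samples, rng_seed=5)
    ids = [s.sample_id for s in train + val + test]
    assert sorted(ids) == sorted(s.sample_id for s in samples)
    pt = [{s.patient_id for s in part} for part in (train, val, test)]
    assert not (pt[0] & pt[1]) and not (pt[0] & pt[2]) and not (pt[1] & pt[2])
    # one patient's tiles never straddle partitions (forced by construction)
    for part in (train, val, test):
        for s in part:
            assert sum(s.patient_id in p for p in pt) == 1


def test_split_deterministic_and_validated():
    samples = _patients(10)
    a = split_by_patient(samples, rng_seed=9)
    b = split_by_patient(samples, rng_seed=9)
    assert [s.sample_id for s in a[0]] == [s.sample_id for s in b[0]]
    with pytest.raises(ValueError):
        split_by_patient(_patients(2))
    with pytest.raises(ValueError):
        split_by_patient(samples, fractions=(0.5, 0.2, 0.2))
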