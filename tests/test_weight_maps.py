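"""Gap/edge penalty maps against a brute-force nearest-two-instances oracle."""

import numpy as np
import pytest

from tamseg.masks import relabel_canonical
from tamseg.nn import Tensor, weighted_softmax_ce
from tamseg.weight_maps import (WeightMap, compute_weight_map,
                                weighted_pixel_cross_entropy)

from conftest import random_label_mask


def oracle_weight_map(labels, proximity_px=10, gap_weight=3.0,
                      edge_weight=0.5, base_weight=1.0):
    """Direct per-pixel evaluation of the gap/edge rules."""
    labels = np.asarray(labels)
    h, w = labels.shape
    ids = sorted(set(labels.ravel()) - {0})
    pix = {k: np.argwhere(labels == k) for k in ids}
    out = np.full((h, w), base_weight, dtype=float)
    for r in range(h):
        for c in range(w):
            if labels[r, c] > 0:
                # edge: 8-adjacent to a non-foreground pixel (or the border
                # is not an edge — erosion treats outside as background-free)
                edge = False
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] == 0:
                            edge = True
                if edge:
                    out[r, c] = base_weight * edge_weight
            else:
                dists = sorted(
                    np.sqrt(((pix[k] - [r, c]) ** 2).sum(axis=1)).min()
                    for k in ids
                )
                if len(dists) >= 2 and dists[0] < proximity_px \
                        and dists[1] < proximity_px:
                    out[r, c] = base_weight * gap_weight
    return out


def test_two_squares_with_corridor():
    """Two 5×5 squares, 4-px corridor: corridor gets the triple penalty."""
    labels = np.zeros((16, 20), np.int32)
    labels[5:10, 2:7] = 1
    labels[5:10, 11:16] = 2
    wm = compute_weight_map(labels)
    expected = oracle_weight_map(labels)
    assert np.allclose(wm.weights, expected)
    # the corridor rows between the squares carry gap weight
    assert np.all(wm.weights[5:10, 7:11] == 3.0)


def test_far_apart_instances_only_edges():
    labels = np.zeros((20, 80), np.int32)
    labels[8:12, 2:6] = 1
    labels[8:12, 60:64] = 2  # > 50 px apart
    wm = compute_weight_map(labels, proximity_px=10)
    assert not np.any(wm.weights == 3.0)
    assert set(np.unique(wm.weights)) == {0.5, 1.0}


def test_single_instance_no_gap():
    labels = np.zeros((12, 12), np.int32)
    labels[4:8, 4:8] = 1
    wm = compute_weight_map(labels)
    assert not np.any(wm.weights > 1.0)


def test_oracle_agreement_randomized(rng):
    for _ in range(8):
        labels = random_label_mask(rng, shape=(28, 28), max_instances=6)
        wm = compute_weight_map(labels, proximity_px=7)
        assert np.allclose(wm.weights, oracle_weight_map(labels, proximity_px=7))


def test_invariant_under_relabel(rng):
    labels = random_label_mask(rng, shape=(32, 32), max_instances=5)
    shuffled = np.where(labels > 0, labels * 7 + 3, 0)  # distinct ids
    a = compute_weight_map(relabel_canonical(labels))
    b = compute_weight_map(shuffled)
    assert np.allclose(a.weights, b.weights)


def test_gap_monotone_in_proximity(rng):
    labels = random_label_mask(rng, shape=(32, 32), max_instances=6)
    prev = None
    for prox in (12, 8, 4, 2):
        gap = compute_weight_map(labels, proximity_px=prox).weights == 3.0
        if prev is not None:
            assert not np.any(gap & ~prev)  # shrinking never adds gap pixels
        prev = gap


def test_parameter_validation():
    labels = np.zeros((4, 4), np.int32)
    with pytest.raises(ValueError):
        compute_weight_map(labels, proximity_px=0)
    with pytest.raises(ValueError):
        compute_weight_map(labels, gap_weight=-1)
    with pytest.raises(ValueError):
        WeightMap(np.zeros((4, 4)))  # non-positive weights


def test_weighted_cross_entropy_properties(rng):
    truth = rng.random((12, 12)) < 0.3
    scores = rng.standard_normal((12, 12, 2))

    # perfect prediction -> ~0 regardless of weights
    perfect = np.stack([np.where(truth, -50.0, 50.0),
                        np.where(truth, 50.0, -50.0)], axis=-1)
    heavy = np.full(truth.shape, 7.0)
    assert weighted_pixel_cross_entropy(perfect, truth, heavy) < 1e-12

    # unit weights equal the plain cross-entropy
    plain = weighted_pixel_cross_entropy(scores, truth)
    unit = weighted_pixel_cross_entropy(scores, truth, np.ones(truth.shape))
    assert plain == pytest.approx(unit, abs=1e-12)

    # linearity: doubling all weights doubles the loss
    w = rng.uniform(0.5, 3.0, truth.shape)
    assert weighted_pixel_cross_entropy(scores, truth, 2 * w) == pytest.approx(
        2 * weighted_pixel_cross_entropy(scores, truth, w), rel=1e-12)

    # channel-first layout accepted
    assert weighted_pixel_cross_entropy(
        np.moveaxis(scores, -1, 0), truth, w) == pytest.approx(
        weighted_pixel_cross_entropy(scores, truth, w), abs=1e-12)


def test_weighted_cross_entropy_errors():
    truth = np.zeros((4, 4), bool)
    with pytest.raises(ValueError):
        weighted_pixel_cross_entropy(np.zeros((4, 4, 2)), np.zeros((5, 5), bool))
    bad = np.zeros((4, 4, 2))
    bad[0, 0, 0] = np.inf
    with pytest.raises(ValueError):
        weighted_pixel_cross_entropy(bad, truth)


def test_matches_training_loss_op(rng):
    """The evaluation CE and the differentiable training CE agree."""
    truth = rng.random((10, 10)) < 0.4
    logits = rng.standard_normal((2, 10, 10)).astype(np.float32)
    w = rng.uniform(0.5, 2.0, (10, 10)).astype(np.float32)
    a = weighted_pixel_cross_entropy(logits, truth, w)
    b = weighted_softmax_ce(Tensor(logits[None]), truth[None].astype(int),
                            w[None]).item()
    assert a == pytest.approx(b, rel=1e-5)
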